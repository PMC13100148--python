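"""End-to-end pipeline driver: simulate/read -> timescales -> classification
-> indices/onsets -> regression -> decoding -> inactivation contrasts.

Each stage writes delimited-text artifacts into the output directory and can
be re-run in isolation from the saved upstream outputs; ``run_meta.json``
records the package version, a hash of the resolved configuration and the
master seed so every run is attributable and repeatable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import child_rng
from .decoding import (
    build_pseudopopulation,
    chance_interval,
    compare_auc,
    delta_auc,
    neuron_dropping_curve,
    normalized_auc,
)
from .indices import compute_all_indices, detect_neuron_onset
from .inference import (
    compare_groups,
    fit_robust_regression,
    indices_design,
    permutation_pvalues,
)
from .modality import classify_by_threshold, excess_mass_test, kde_threshold
from .synth import SimConfig, simulate_experiment
from .table import SpikeTable, read_spike_table, write_spike_table
from .timescales import baseline_descriptives, bin_spikes, estimate_timescales

log = logging.getLogger("spiketau")


@dataclass
class RunConfig:
    """Pipeline configuration; stage parameters default to the standard
    analysis values (10 ms bins, 200-500 ms baseline, R^2 >= 0.3, 50-200 /
    200-500 ms windows, 10,000 permutations, sizes 3-120 with 500
    iterations and 1000 chance simulations)."""

    out_dir: str | Path = "results"
    input_dir: str | Path | None = None  # read a SpikeTable instead of simulating
    sim: SimConfig | None = None
    seed: int = 0
    bin_width: float = 10.0
    baseline_window: tuple[float, float] = (200.0, 500.0)
    r2_min: float = 0.3
    transient_window: tuple[float, float] = (50.0, 200.0)
    sustained_window: tuple[float, float] = (200.0, 500.0)
    n_perm: int = 10_000
    n_bootstrap: int = 500
    decoding_sizes: tuple[int, int] = (3, 120)
    n_iterations: int = 500
    n_chance_sims: int = 1000
    run_classification: bool = True
    run_regression: bool = True
    run_decoding: bool = True
    decoding_contrasts: tuple = (
        ("detectability", "single", "transient"),
        ("detectability", "popout", "sustained"),
    )
    conditions: tuple[str, ...] = ("control", "inactivation")
    log_level: str = "INFO"

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_meta(out: Path, config: RunConfig) -> None:
    (out / "run_meta.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            indent=2,
        )
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the summary dictionary that is also
    written to ``summary.json``.  Stage outputs land in ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_meta(out, config)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    # ------------------------------------------------------------- input stage
    if config.input_dir is not None:
        table = read_spike_table(config.input_dir)
        log.info("read spike table from %s", config.input_dir)
    else:
        sim = config.sim or SimConfig(seed=config.seed)
        table, truth = simulate_experiment(sim)
        write_spike_table(table, out / "spike_table")
        truth.params.to_csv(out / "spike_table" / "ground_truth.csv", index=False)
        (out / "spike_table" / "sim_config.json").write_text(
            json.dumps(dataclasses.asdict(sim), indent=2, default=str)
        )
        log.info("simulated %d neurons", len(table.neurons))
    conditions = [c for c in config.conditions if c in set(table.trials["condition"])]
    summary["n_neurons"] = int(len(table.neurons))
    summary["conditions"] = conditions

    # -------------------------------------------------------- timescales stage
    ts_frames = []
    for condition in conditions:
        ts = estimate_timescales(
            table,
            condition=condition,
            baseline_window=config.baseline_window,
            bin_width=config.bin_width,
            r2_min=config.r2_min,
        )
        ts_frames.append(ts)
    timescales = pd.concat(ts_frames, ignore_index=True)
    timescales.to_csv(out / "timescales.csv", index=False)
    kept = timescales[timescales["kept"]]
    summary["timescales"] = {
        c: {
            "n_kept": int((kept["condition"] == c).sum()),
            "n_excluded": int(((timescales["condition"] == c) & ~timescales["kept"]).sum()),
            "median_tau": float(kept.loc[kept["condition"] == c, "tau_ms"].median()),
        }
        for c in conditions
    }

    # ------------------------------------------------------ descriptives stage
    desc_rows = []
    for condition in conditions:
        for nid in table.neuron_ids():
            tids = table.trials_for(nid, condition=condition)["trial_id"]
            binned = bin_spikes(
                table.spike_trains(nid, tids), config.baseline_window, config.bin_width
            )
            d = baseline_descriptives(binned)
            desc_rows.append({"neuron_id": int(nid), "condition": condition, **d})
    descriptives = pd.DataFrame(desc_rows)
    descriptives.to_csv(out / "baseline_descriptives.csv", index=False)

    # ---------------------------------------------------- classification stage
    classes = None
    if config.run_classification:
        ctrl = kept[kept["condition"] == conditions[0]]
        taus = ctrl["tau_ms"].to_numpy()
        stat, p = excess_mass_test(
            taus, n_bootstrap=config.n_bootstrap, rng=child_rng(config.seed, 10)
        )
        kt = kde_threshold(taus)
        modality = {
            "statistic": stat,
            "p_value": p,
            "n_bootstrap": config.n_bootstrap,
            "threshold_ms": kt.threshold,
            "bandwidth_ms": kt.bandwidth,
            "unimodal": kt.unimodal,
        }
        (out / "modality.json").write_text(json.dumps(modality, indent=2))
        summary["modality"] = modality
        if not kt.unimodal:
            frames = []
            for condition in conditions:
                sub = kept[kept["condition"] == condition]
                frames.append(
                    pd.DataFrame(
                        {
                            "neuron_id": sub["neuron_id"].to_numpy(),
                            "condition": condition,
                            "label": classify_by_threshold(
                                sub["tau_ms"].to_numpy(), kt.threshold
                            ),
                        }
                    )
                )
            classes = pd.concat(frames, ignore_index=True)
            classes.to_csv(out / "classes.csv", index=False)
            ctrl_classes = classes[classes["condition"] == conditions[0]]
            summary["class_sizes"] = (
                ctrl_classes["label"].value_counts().to_dict()
            )
    else:
        log.info("classification disabled; class-stratified stages will be skipped")

    # ----------------------------------------------------- indices/onset stage
    indices, rf_map, rf_failures = compute_all_indices(
        table, conditions=conditions, rf_condition=conditions[0]
    )
    indices.to_csv(out / "indices.csv", index=False)
    onset_rows = []
    for nid in rf_map:
        for condition in conditions:
            for stim_type in ("single", "popout"):
                o = detect_neuron_onset(
                    table,
                    nid,
                    condition=condition,
                    stimulus_type=stim_type,
                    bin_width=config.bin_width,
                    baseline_window=config.baseline_window,
                )
                onset_rows.append(
                    {
                        "neuron_id": nid,
                        "condition": condition,
                        "stimulus_type": stim_type,
                        "onset_ms": o.onset_ms,
                        "detected": o.detected,
                    }
                )
    onsets = pd.DataFrame(onset_rows)
    onsets.to_csv(out / "onsets.csv", index=False)
    summary["rf_failures"] = rf_failures
    summary["onset_detection_rate"] = float(onsets["detected"].mean())

    # --------------------------------------------------------- regression stage
    if config.run_regression:
        regression = {}
        for condition in conditions:
            sub_idx = indices[indices["condition"] == condition]
            sub_tau = kept[kept["condition"] == condition].set_index("neuron_id")["tau_ms"]
            rates = descriptives[descriptives["condition"] == condition].set_index(
                "neuron_id"
            )["rate"]
            design = indices_design(sub_idx, rates)
            design, response = design.align(sub_tau, join="inner", axis=0)
            try:
                fit = fit_robust_regression(design, response)
                pvals = permutation_pvalues(
                    design,
                    response,
                    n_perm=config.n_perm,
                    rng=child_rng(config.seed, 20, conditions.index(condition)),
                )
                regression[condition] = {
                    "coefficients": fit.params.to_dict(),
                    "perm_p": pvals.to_dict(),
                    "vif": fit.vif.to_dict(),
                    "n": fit.n_obs,
                    "residual_normality_p": fit.residual_normality_p,
                }
            except ValueError as err:
                regression[condition] = {"error": str(err)}
        (out / "regression.json").write_text(json.dumps(regression, indent=2))
        summary["regression"] = regression

    # ----------------------------------------------------------- decoding stage
    if config.run_decoding and classes is not None:
        ctrl_classes = classes[classes["condition"] == conditions[0]]
        label_map = dict(zip(ctrl_classes["neuron_id"], ctrl_classes["label"]))
        curves_rows, auc_rows, contrast_rows = [], [], []
        for task, stim_type, period in config.decoding_contrasts:
            aucs = {}
            for cls in ("short", "long"):
                ids = [nid for nid, lab in label_map.items() if lab == cls and nid in rf_map]
                for condition in conditions:
                    rng = child_rng(
                        config.seed,
                        30,
                        conditions.index(condition),
                        ("short", "long").index(cls),
                        config.decoding_contrasts.index((task, stim_type, period)),
                    )
                    try:
                        pop = build_pseudopopulation(
                            table,
                            rf_map,
                            task,
                            period,
                            stimulus_type=stim_type,
                            condition=condition,
                            neuron_ids=ids,
                            rng=rng,
                        )
                    except ValueError as err:
                        log.warning("decoding %s/%s/%s %s: %s", task, stim_type, period, cls, err)
                        continue
                    sizes = [
                        s
                        for s in range(
                            config.decoding_sizes[0],
                            config.decoding_sizes[1] + 1,
                            1 if task == "detectability" else 2,
                        )
                    ]
                    curve = neuron_dropping_curve(
                        pop, sizes=sizes, n_iterations=config.n_iterations, rng=rng
                    )
                    lower, upper = chance_interval(
                        pop, curve.sizes, n_sims=config.n_chance_sims, rng=rng
                    )
                    try:
                        auc = normalized_auc(curve, upper, rng=rng)
                    except ValueError as err:
                        log.warning(
                            "decoding %s/%s/%s %s: %s", task, stim_type, period, cls, err
                        )
                        continue
                    aucs[(cls, condition)] = auc
                    for si, size in enumerate(curve.sizes):
                        for it in range(curve.accuracies.shape[1]):
                            curves_rows.append(
                                {
                                    "task": task,
                                    "stimulus_type": stim_type,
                                    "period": period,
                                    "class": cls,
                                    "condition": condition,
                                    "size": int(size),
                                    "iteration": it,
                                    "accuracy": curve.accuracies[si, it],
                                }
                            )
                    for gi, v in enumerate(auc.auc_samples):
                        auc_rows.append(
                            {
                                "task": task,
                                "stimulus_type": stim_type,
                                "period": period,
                                "class": cls,
                                "condition": condition,
                                "group_id": gi,
                                "auc_normalized": v,
                            }
                        )
            # class contrast under control; inactivation deltas when available
            key = f"{task}:{stim_type}:{period}"
            if ("short", conditions[0]) in aucs and ("long", conditions[0]) in aucs:
                res = compare_auc(aucs[("short", conditions[0])], aucs[("long", conditions[0])])
                contrast_rows.append(
                    {
                        "contrast": f"{key}:short_vs_long:{conditions[0]}",
                        "test": res.test,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "effect_size": res.effect_size,
                    }
                )
            if len(conditions) > 1:
                deltas = {}
                for cls in ("short", "long"):
                    if (cls, conditions[0]) in aucs and (cls, conditions[1]) in aucs:
                        deltas[cls] = delta_auc(aucs[(cls, conditions[0])], aucs[(cls, conditions[1])])
                if set(deltas) == {"short", "long"}:
                    res = compare_groups(deltas["short"], deltas["long"], test="rank-sum")
                    contrast_rows.append(
                        {
                            "contrast": f"{key}:delta_auc_short_vs_long",
                            "test": res.test,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "effect_size": res.effect_size,
                        }
                    )
        pd.DataFrame(curves_rows).to_csv(out / "decoding_curves.csv", index=False)
        pd.DataFrame(auc_rows).to_csv(out / "auc.csv", index=False)
        contrasts = pd.DataFrame(contrast_rows)
        if len(contrasts):
            contrasts["p_adjusted"] = np.nan
            mask = contrasts["p_value"].notna()
            from .inference import fdr_adjust

            contrasts.loc[mask, "p_adjusted"] = fdr_adjust(
                contrasts.loc[mask, "p_value"].to_numpy()
            )
        contrasts.to_csv(out / "decoding_contrasts.csv", index=False)
        summary["decoding_contrasts"] = contrast_rows
    elif config.run_decoding:
        log.info("decoding skipped: classification unavailable")
        summary["decoding_skipped"] = "classification unavailable"

    # --------------------------------------------------- inactivation contrasts
    if len(conditions) > 1:
        inact_rows = []
        tau_wide = kept.pivot_table(index="neuron_id", columns="condition", values="tau_ms")
        tau_wide = tau_wide.dropna()
        if len(tau_wide) >= 5:
            res = compare_groups(
                tau_wide[conditions[1]], tau_wide[conditions[0]], test="signed-rank", paired=True
            )
            inact_rows.append({"contrast": "tau_inactivation_vs_control", **res.__dict__})
            if classes is not None:
                lbl = classes[classes["condition"] == conditions[0]].set_index("neuron_id")[
                    "label"
                ]
                delta = (tau_wide[conditions[1]] - tau_wide[conditions[0]]).rename("delta")
                joined = pd.concat([delta, lbl], axis=1).dropna()
                if joined["label"].nunique() == 2:
                    res = compare_groups(
                        joined.loc[joined["label"] == "short", "delta"],
                        joined.loc[joined["label"] == "long", "delta"],
                        test="rank-sum",
                    )
                    inact_rows.append(
                        {"contrast": "delta_tau_short_vs_long", **res.__dict__}
                    )
        rate_wide = descriptives.pivot_table(
            index="neuron_id", columns="condition", values="rate"
        ).dropna()
        if len(rate_wide) >= 5 and len(tau_wide) >= 5:
            shared = tau_wide.index.intersection(rate_wide.index)
            from .inference import associate

            rho, p = associate(
                (tau_wide.loc[shared, conditions[1]] - tau_wide.loc[shared, conditions[0]]),
                (rate_wide.loc[shared, conditions[1]] - rate_wide.loc[shared, conditions[0]]),
            )
            inact_rows.append(
                {
                    "contrast": "delta_tau_vs_delta_rate",
                    "test": "spearman",
                    "statistic": rho,
                    "p_value": p,
                    "effect_size": rho,
                    "n1": len(shared),
                    "n2": len(shared),
                }
            )
        comparisons = pd.DataFrame(inact_rows)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        summary["inactivation_contrasts"] = inact_rows

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
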