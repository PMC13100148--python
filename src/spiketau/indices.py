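"""Receptive fields, single/popout visual indices, and onset latencies.

The receptive field (RF) of a neuron is the set of stimulus locations whose
mean single-stimulus response exceeds 95% of the maximum across locations;
the four far-right-column grid locations are the designated Out-RF controls.
The visual index for a stimulus type and analysis period is the normalized
rate difference

    index = (mean In-RF rate - mean Out-RF rate) / (sum of the two)

computed for transient (50-200 ms) and sustained (200-500 ms) windows after
stimulus onset.  Onset latency is the leading bin of the first run of two
consecutive post-stimulus bins whose trial-mean count exceeds the baseline
mean + 2 SD threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rate_in_window
from .table import SpikeTable
from .timescales import BinnedCounts

DEFAULT_RESPONSE_WINDOW = (50.0, 500.0)  # ms after stimulus onset, spans both periods
TRANSIENT_WINDOW = (50.0, 200.0)
SUSTAINED_WINDOW = (200.0, 500.0)
RF_FRACTION = 0.95


class RFError(ValueError):
    """Raised when a receptive field cannot be estimated."""


@dataclass
class RFEstimate:
    in_rf: set[int]
    out_rf: set[int]
    response_by_location: dict[int, float]  # spikes/s
    overlap_removed: set[int] = field(default_factory=set)


def _out_rf_locations(table: SpikeTable) -> set[int]:
    meta = table.meta.get("out_rf_locations")
    if meta is not None:
        return set(int(v) for v in meta)
    cols, rows = table.meta.get("grid_shape", (6, 4))
    return {r * cols + cols for r in range(rows)}


def estimate_rf(
    table: SpikeTable,
    neuron_id: int,
    response_window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
    condition: str = "control",
    out_rf: set[int] | None = None,
    rf_fraction: float = RF_FRACTION,
) -> RFEstimate:
    """Estimate the RF from single-stimulus responses.

    Locations responding strictly above ``rf_fraction`` of the maximum are
    In-RF; Out-RF is the fixed far-right column.  Out-RF ids are removed
    from the In-RF set (recorded in ``overlap_removed``); an In-RF that is
    empty after removal raises :class:`RFError`.
    """
    out_rf = set(out_rf) if out_rf is not None else _out_rf_locations(table)
    n_locations = int(table.meta.get("n_locations", 24))
    trials = table.trials_for(neuron_id, condition=condition, stimulus_type="single")
    response: dict[int, float] = {}
    missing = []
    for loc in range(1, n_locations + 1):
        t = trials[trials["stimulus_location"] == loc]
        if len(t) == 0:
            missing.append(loc)
            continue
        trains = table.spike_trains(neuron_id, t["trial_id"])
        windows = [
            (on + response_window[0], on + response_window[1])
            for on in t["stimulus_on"].to_numpy(dtype=float)
        ]
        response[loc] = float(
            np.mean([rate_in_window(tr, w) for tr, w in zip(trains, windows)])
        )
    if missing:
        raise RFError(f"neuron {neuron_id}: no single-stimulus trials at locations {missing}")
    peak = max(response.values())
    in_rf = {loc for loc, r in response.items() if r > rf_fraction * peak}
    overlap = in_rf & out_rf
    in_rf -= out_rf
    if not in_rf:
        raise RFError(f"neuron {neuron_id}: RF inside Out-RF column")
    return RFEstimate(in_rf=in_rf, out_rf=out_rf, response_by_location=response,
                      overlap_removed=overlap)


def compute_index(in_mean: float, out_mean: float) -> float:
    """Normalized rate difference ``(in - out) / (in + out)``; NaN when the
    denominator is zero."""
    if in_mean < 0 or out_mean < 0:
        raise ValueError("mean rates must be >= 0")
    total = in_mean + out_mean
    if total == 0:
        return float("nan")
    return (in_mean - out_mean) / total


def compute_index_set(
    table: SpikeTable,
    neuron_id: int,
    rf: RFEstimate,
    condition: str = "control",
    transient_window: tuple[float, float] = TRANSIENT_WINDOW,
    sustained_window: tuple[float, float] = SUSTAINED_WINDOW,
) -> pd.DataFrame:
    """Indices for both stimulus types and both periods of one condition.

    Windows are half-open, relative to each trial's stimulus onset; per-trial
    rates are averaged within the In-RF and Out-RF location sets before
    forming the index.
    """
    rows = []
    for stim_type in ("single", "popout"):
        trials = table.trials_for(neuron_id, condition=condition, stimulus_type=stim_type)
        loc = trials["stimulus_location"].to_numpy()
        in_mask = np.isin(loc, list(rf.in_rf))
        out_mask = np.isin(loc, list(rf.out_rf))
        for period, window in (("transient", transient_window), ("sustained", sustained_window)):
            means = {}
            for name, mask in (("in", in_mask), ("out", out_mask)):
                sub = trials[mask]
                if len(sub) == 0:
                    means[name] = np.nan
                    continue
                trains = table.spike_trains(neuron_id, sub["trial_id"])
                ons = sub["stimulus_on"].to_numpy(dtype=float)
                means[name] = float(
                    np.mean(
                        [
                            rate_in_window(tr, (on + window[0], on + window[1]))
                            for tr, on in zip(trains, ons)
                        ]
                    )
                )
            idx = (
                compute_index(means["in"], means["out"])
                if np.isfinite(means["in"]) and np.isfinite(means["out"])
                else float("nan")
            )
            rows.append(
                {
                    "neuron_id": int(neuron_id),
                    "condition": condition,
                    "stimulus_type": stim_type,
                    "period": period,
                    "in_mean": means["in"],
                    "out_mean": means["out"],
                    "index": idx,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OnsetResult:
    onset_ms: float | None  # latency from stimulus onset
    threshold: float  # spikes per bin
    detected: bool


def detect_onset(
    post_counts: BinnedCounts,
    baseline_counts: BinnedCounts,
    min_consecutive: int = 2,
) -> OnsetResult:
    """Onset = leading bin of the first run of ``min_consecutive`` post-stimulus
    bins whose trial-mean count strictly exceeds baseline mean + 2 SD.

    The SD is taken across baseline bins of the trial-averaged counts
    (population SD), giving one stable threshold per neuron.  With constant
    zero baseline the threshold is 0 and any active bin pair triggers.
    """
    if baseline_counts.n_bins < 2 or post_counts.n_bins < min_consecutive:
        raise ValueError("need >= 2 baseline bins and enough post-stimulus bins")
    base = baseline_counts.counts.mean(axis=0)
    threshold = float(base.mean() + 2.0 * base.std(ddof=0))
    post = post_counts.counts.mean(axis=0)
    above = post > threshold
    run = 0
    for j, hit in enumerate(above):
        run = run + 1 if hit else 0
        if run >= min_consecutive:
            lead = j - min_consecutive + 1
            onset = post_counts.window[0] + lead * post_counts.bin_width
            return OnsetResult(onset_ms=float(onset), threshold=threshold, detected=True)
    return OnsetResult(onset_ms=None, threshold=threshold, detected=False)


def detect_neuron_onset(
    table: SpikeTable,
    neuron_id: int,
    condition: str = "control",
    stimulus_type: str = "single",
    bin_width: float = 10.0,
    baseline_window: tuple[float, float] = (200.0, 500.0),
    search_ms: float = 500.0,
) -> OnsetResult:
    """Bin a neuron's trials and run onset detection relative to stimulus onset."""
    from .timescales import bin_spikes

    trials = table.trials_for(neuron_id, condition=condition, stimulus_type=stimulus_type)
    if len(trials) == 0:
        raise ValueError(f"neuron {neuron_id}: no {stimulus_type} trials in {condition}")
    trains = table.spike_trains(neuron_id, trials["trial_id"])
    ons = trials["stimulus_on"].to_numpy(dtype=float)
    aligned = [tr - on for tr, on in zip(trains, ons)]
    base = bin_spikes(trains, baseline_window, bin_width)  # absolute pre-stimulus window
    post = bin_spikes(aligned, (0.0, search_ms), bin_width)
    return detect_onset(post, base)


def compute_all_indices(
    table: SpikeTable,
    conditions=("control",),
    rf_condition: str = "control",
    neuron_ids=None,
) -> tuple[pd.DataFrame, dict[int, RFEstimate], dict[int, str]]:
    """Indices for every neuron and condition; RFs estimated once from
    ``rf_condition`` trials and reused across conditions so the In/Out
    definition stays fixed.  Returns (indices, rf map, per-neuron failures).
    """
    frames, rfs, failures = [], {}, {}
    if neuron_ids is None:
        neuron_ids = table.neuron_ids()
    for nid in neuron_ids:
        try:
            rf = estimate_rf(table, nid, condition=rf_condition)
        except RFError as err:
            failures[int(nid)] = str(err)
            continue
        rfs[int(nid)] = rf
        for condition in conditions:
            frames.append(compute_index_set(table, nid, rf, condition=condition))
    indices = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["neuron_id", "condition", "stimulus_type", "period",
                     "in_mean", "out_mean", "index"]
        )
    )
    return indices, rfs, failures
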