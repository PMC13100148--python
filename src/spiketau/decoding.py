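"""Pseudo-population neuron-dropping decoding.

Neurons recorded separately are combined into pseudo-populations by matching
trial labels: for each resampling iteration a subset of neurons is drawn,
each neuron's class-matched trials are independently shuffled, and trial
``t`` of every neuron is concatenated into pseudo-trial ``t``.  Features are
per-trial firing rates in the transient or sustained window.  Two tasks are
supported: binary detectability (stimulus In-RF vs Out-RF) and 24-way
discriminability (which grid location).  Each decode standardizes the
training split, projects onto the top three principal components, and
trains a linear max-margin (SVM) classifier.

Accuracy-vs-population-size curves (3..120 neurons; 500 iterations per
size) are summarized by the area between the mean curve and the upper bound
of a simulated binomial chance band, normalized by the maximum attainable
area, with an AUC sampling distribution from partitioning iterations into
100 non-overlapping groups of 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._utils import rate_in_window
from .indices import RFEstimate
from .inference import compare_groups, fdr_adjust
from .table import SpikeTable

MIN_TRIALS_PER_CLASS = 20
DEFAULT_N_ITERATIONS = 500
DEFAULT_N_CHANCE_SIMS = 1000
DEFAULT_SIZES = (3, 120)
TRAIN_FRACTION = 0.7
N_COMPONENTS = 3


@dataclass
class PseudoPopulation:
    """Balanced per-neuron, per-class trial features.

    ``features[i, c, t]`` is the firing rate of neuron ``i`` on its ``t``-th
    (balanced) trial of class ``c``; every neuron contributes the same
    number of trials per class.
    """

    features: np.ndarray  # (n_neurons, n_classes, n_trials_per_class)
    neuron_ids: np.ndarray
    class_labels: np.ndarray
    task: str  # detectability | discriminability
    period: str
    excluded: dict[int, str]

    @property
    def n_neurons(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return self.features.shape[1]

    @property
    def trials_per_class(self) -> int:
        return self.features.shape[2]

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_classes


def default_sizes(task: str, lo: int = DEFAULT_SIZES[0], hi: int = DEFAULT_SIZES[1]) -> np.ndarray:
    """Population-size grid: step 1 for detectability, 2 for discriminability."""
    step = 1 if task == "detectability" else 2
    return np.arange(lo, hi + 1, step)


def build_pseudopopulation(
    table: SpikeTable,
    rf_map: dict[int, RFEstimate],
    task: str,
    period: str,
    stimulus_type: str = "single",
    condition: str = "control",
    neuron_ids=None,
    window: tuple[float, float] | None = None,
    min_trials: int = MIN_TRIALS_PER_CLASS,
    rng: np.random.Generator | None = None,
) -> PseudoPopulation:
    """Assemble a balanced pseudo-population.

    Detectability labels trials In-RF (1) vs Out-RF (0) by stimulus
    location; discriminability labels every grid location.  Neurons with
    fewer than ``min_trials`` trials in any class are excluded (recorded),
    and every class is subsampled to the global minimum class count.
    """
    if task not in ("detectability", "discriminability"):
        raise ValueError("task must be 'detectability' or 'discriminability'")
    rng = rng or np.random.default_rng()
    if window is None:
        key = f"{period}_window"
        base = table.meta.get(key, (50.0, 200.0) if period == "transient" else (200.0, 500.0))
        window = (float(base[0]), float(base[1]))
    if neuron_ids is None:
        neuron_ids = list(rf_map)

    per_neuron: dict[int, dict[int, np.ndarray]] = {}
    excluded: dict[int, str] = {}
    class_values: list[int] | None = None
    for nid in neuron_ids:
        trials = table.trials_for(nid, condition=condition, stimulus_type=stimulus_type)
        loc = trials["stimulus_location"].to_numpy()
        if task == "detectability":
            rf = rf_map[int(nid)]
            labels = np.where(
                np.isin(loc, list(rf.in_rf)), 1, np.where(np.isin(loc, list(rf.out_rf)), 0, -1)
            )
        else:
            labels = loc
        keep = labels >= 0 if task == "detectability" else np.ones(len(loc), bool)
        sub = trials[keep]
        labels = labels[keep]
        trains = table.spike_trains(nid, sub["trial_id"])
        ons = sub["stimulus_on"].to_numpy(dtype=float)
        rates = np.array(
            [rate_in_window(tr, (on + window[0], on + window[1])) for tr, on in zip(trains, ons)]
        )
        classes = np.unique(labels)
        if task == "detectability" and set(classes) != {0, 1}:
            excluded[int(nid)] = "missing In-RF or Out-RF trials"
            continue
        counts = {int(c): int(np.sum(labels == c)) for c in classes}
        if min(counts.values()) < min_trials:
            excluded[int(nid)] = f"fewer than {min_trials} trials in a class"
            continue
        per_neuron[int(nid)] = {int(c): rates[labels == c] for c in classes}
        if class_values is None:
            class_values = sorted(int(c) for c in classes)

    if not per_neuron:
        raise ValueError("no neuron passed the per-class trial floor")
    m = min(min(len(v) for v in d.values()) for d in per_neuron.values())
    kept_ids = np.array(sorted(per_neuron), dtype=int)
    features = np.empty((len(kept_ids), len(class_values), m))
    for i, nid in enumerate(kept_ids):
        for c, cls in enumerate(class_values):
            pool = per_neuron[nid][cls]
            features[i, c, :] = pool[rng.choice(len(pool), size=m, replace=False)]
    return PseudoPopulation(
        features=features,
        neuron_ids=kept_ids,
        class_labels=np.array(class_values),
        task=task,
        period=period,
        excluded=excluded,
    )


def _test_counts(trials_per_class: int, n_classes: int) -> int:
    n_train = int(round(TRAIN_FRACTION * trials_per_class))
    n_train = min(max(n_train, 1), trials_per_class - 1)
    return (trials_per_class - n_train) * n_classes


def decode_once(
    population: PseudoPopulation,
    n_neurons: int,
    rng: np.random.Generator,
    permute_labels: bool = False,
) -> float:
    """One decoding iteration: sample neurons, assemble pseudo-trials, split
    stratified 70/30, standardize + 3-component PCA (training statistics
    only) and score a linear SVM on the held-out pseudo-trials."""
    if n_neurons > population.n_neurons:
        raise ValueError("n_neurons exceeds available neurons")
    m = population.trials_per_class
    k = population.n_classes
    idx = rng.choice(population.n_neurons, size=n_neurons, replace=False)
    feats = population.features[idx]  # (n_neurons, k, m)
    # shuffle trials independently per neuron and class -> pseudo-trials
    X = np.empty((k * m, n_neurons))
    y = np.repeat(np.arange(k), m)
    for j in range(n_neurons):
        for c in range(k):
            X[c * m : (c + 1) * m, j] = feats[j, c, rng.permutation(m)]
    if permute_labels:
        y = y[rng.permutation(len(y))]
    # split stratified on the labels as given (after any permutation), so the
    # train/test class proportions stay balanced even under the null
    n_train = int(round(TRAIN_FRACTION * m))
    n_train = min(max(n_train, 1), m - 1)
    for _ in range(10):
        train_mask = np.zeros(k * m, dtype=bool)
        for c in np.unique(y):
            members = np.flatnonzero(y == c)
            take = min(max(int(round(TRAIN_FRACTION * len(members))), 1),
                       len(members) - 1)
            train_mask[rng.permutation(members)[:take]] = True
        if len(np.unique(y[~train_mask])) == len(np.unique(y)) and len(
            np.unique(y[train_mask])
        ) == len(np.unique(y)):
            break
    else:
        raise RuntimeError("could not produce a split containing every class")
    scaler = StandardScaler().fit(X[train_mask])
    Xtr = scaler.transform(X[train_mask])
    Xte = scaler.transform(X[~train_mask])
    n_comp = min(N_COMPONENTS, Xtr.shape[1], Xtr.shape[0] - 1)
    pca = PCA(n_components=n_comp).fit(Xtr)
    clf = LinearSVC(C=1.0, max_iter=5000).fit(pca.transform(Xtr), y[train_mask])
    return float(clf.score(pca.transform(Xte), y[~train_mask]))


@dataclass
class DecodingCurve:
    sizes: np.ndarray
    accuracies: np.ndarray  # (n_sizes, n_iterations)
    task: str
    period: str
    chance_lower: np.ndarray | None = None
    chance_upper: np.ndarray | None = None

    @property
    def mean_curve(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)


def neuron_dropping_curve(
    population: PseudoPopulation,
    sizes=None,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    rng: np.random.Generator | None = None,
    permute_labels: bool = False,
) -> DecodingCurve:
    """Accuracy samples across population sizes (``n_iterations`` per size).

    Sizes beyond the available neuron count are truncated with a warning.
    """
    import warnings

    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    rng = rng or np.random.default_rng()
    if sizes is None:
        sizes = default_sizes(population.task)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.max() > population.n_neurons:
        warnings.warn(
            f"truncating sizes to the {population.n_neurons} available neurons"
        )
        sizes = sizes[sizes <= population.n_neurons]
    acc = np.empty((len(sizes), n_iterations))
    for si, size in enumerate(sizes):
        for it in range(n_iterations):
            acc[si, it] = decode_once(population, int(size), rng, permute_labels=permute_labels)
    return DecodingCurve(sizes=sizes, accuracies=acc, task=population.task,
                         period=population.period)


def chance_interval(
    population: PseudoPopulation,
    sizes,
    n_sims: int = DEFAULT_N_CHANCE_SIMS,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-size 95% chance band: 2.5th/97.5th percentiles of binomial
    accuracy draws at the task's chance probability, with the test-trial
    count obtained by simulating the sampling/splitting procedure."""
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = rng or np.random.default_rng()
    sizes = np.asarray(sizes, dtype=int)
    p0 = population.chance_level
    n_test = _test_counts(population.trials_per_class, population.n_classes)
    lower = np.empty(len(sizes))
    upper = np.empty(len(sizes))
    for si in range(len(sizes)):
        draws = rng.binomial(n_test, p0, size=n_sims) / n_test
        lower[si] = np.percentile(draws, 2.5)
        upper[si] = np.percentile(draws, 97.5)
    return lower, upper


@dataclass
class AUCResult:
    auc_raw: float
    auc_normalized: float
    auc_samples: np.ndarray  # normalized AUC per iteration group
    n_groups: int


def normalized_auc(
    curve: DecodingCurve,
    chance_upper: np.ndarray,
    n_groups: int = 100,
    rng: np.random.Generator | None = None,
) -> AUCResult:
    """Area between the accuracy curve and the chance upper bound.

    Accuracies are clipped below at the bound before trapezoidal
    integration; normalization divides by the area between perfect accuracy
    and the bound.  The sampling distribution partitions iterations into
    ``n_groups`` non-overlapping groups and integrates each group's mean
    curve.
    """
    rng = rng or np.random.default_rng()
    chance_upper = np.asarray(chance_upper, dtype=float)
    if len(chance_upper) != len(curve.sizes):
        raise ValueError("curve and chance bound must share the size grid")
    if len(curve.sizes) < 2:
        raise ValueError("need at least two population sizes to integrate an AUC")
    if np.any(chance_upper >= 1.0):
        raise ValueError("chance upper bound must be < 1 everywhere")
    x = curve.sizes.astype(float)
    max_area = float(np.trapezoid(1.0 - chance_upper, x))

    def area(mean_curve: np.ndarray) -> float:
        clipped = np.maximum(mean_curve, chance_upper)
        return float(np.trapezoid(clipped - chance_upper, x))

    raw = area(curve.mean_curve)
    n_iter = curve.accuracies.shape[1]
    n_groups_eff = min(n_groups, n_iter)
    perm = rng.permutation(n_iter)
    groups = np.array_split(perm, n_groups_eff)
    samples = np.array(
        [area(curve.accuracies[:, g].mean(axis=1)) / max_area for g in groups]
    )
    return AUCResult(
        auc_raw=raw,
        auc_normalized=raw / max_area,
        auc_samples=samples,
        n_groups=n_groups_eff,
    )


def compare_curves(curve_a: DecodingCurve, curve_b: DecodingCurve) -> pd.DataFrame:
    """Per-size two-sided rank-sum tests across iteration samples, with
    Benjamini-Hochberg adjustment across sizes."""
    if not np.array_equal(curve_a.sizes, curve_b.sizes):
        raise ValueError("size grids differ")
    rows = []
    for si, size in enumerate(curve_a.sizes):
        res = compare_groups(curve_a.accuracies[si], curve_b.accuracies[si], test="rank-sum")
        rows.append(
            {
                "size": int(size),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "effect_size": res.effect_size,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = fdr_adjust(out["p_value"].to_numpy())
    return out


def compare_auc(a: AUCResult, b: AUCResult):
    """Rank-sum comparison of two normalized-AUC sampling distributions."""
    return compare_groups(a.auc_samples, b.auc_samples, test="rank-sum")


def delta_auc(control: AUCResult, inactivation: AUCResult) -> np.ndarray:
    """Relative AUC change per matched resampling group:
    ``(inactivation - control) / control``."""
    n = min(len(control.auc_samples), len(inactivation.auc_samples))
    c = control.auc_samples[:n]
    i = inactivation.auc_samples[:n]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (i - c) / c
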