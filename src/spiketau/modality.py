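"""Bimodality testing and short/long classification of timescales.

Two tools:

* the **excess-mass test** of unimodality.  Its statistic is the extra
  probability mass the best two-mode allocation captures over the best
  one-mode allocation, maximized over the mass level; it equals twice the
  dip statistic (the sup-distance from the empirical CDF to the nearest
  unimodal CDF), which is how it is computed here.  The p-value is
  calibrated by a smoothed bootstrap from the closest unimodal density:
  a Gaussian KDE at the critical bandwidth (the smallest bandwidth making
  the density unimodal), variance-rescaled.

* **KDE threshold classification**: a Gaussian KDE (Silverman bandwidth, on
  the linear timescale axis) of the pooled timescale distribution; the
  global minimum between the two tallest modes splits neurons into
  short-timescale and long-timescale groups.

The dip is computed from its tube characterization: the empirical CDF
``F_n`` is within sup-distance ``t`` of some unimodal CDF exactly when a
nondecreasing, convex-then-concave path fits inside the tube
``[F_n - t, F_n + t]`` (evaluated at both corners of every CDF step).  For a
given ``t``, feasibility is decided in O(n^2): the smallest height at which
a convex path obeying the tube can arrive at each point (bounded by extremal
tangent lines through earlier ceiling/floor corners), the largest height at
which a concave path can depart, and a scan over candidate mode positions
joining the two.  The dip is the critical ``t`` located by bisection, and
the implementation is validated in the test suite against an independent
linear-programming transcription of the dip's definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # optional JIT: pure-python fallback keeps behaviour identical
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "dip_statistic",
    "excess_mass_stat",
    "excess_mass_test",
    "critical_bandwidth",
    "kde_threshold",
    "classify_by_threshold",
    "modality_analysis",
    "KDEThreshold",
    "ModalityResult",
]


# ------------------------------------------------------------------- dip core


def _step_corners(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct sorted values with lower (U) and upper (L) empirical-CDF corners.

    For distinct x the empirical CDF jumps from U_i = i/n (left limit) to
    L_i = (i+1)/n; ties collapse to one x carrying the extreme corners.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    distinct, first = np.unique(x, return_index=True)
    last = np.r_[first[1:], n] - 1
    U = first / n  # CDF just below each distinct value
    L = (last + 1) / n  # CDF at each distinct value
    return distinct, U, L


@_njit(cache=True)
def _unimodal_path_exists(xs, lo, up):  # pragma: no cover - exercised via dip_statistic
    """True iff a nondecreasing convex-then-concave path passes through every
    vertical gate ``[lo_i, up_i]`` at ``xs_i`` (gates must be nondecreasing).

    ``A_i``: the smallest height a convex path through gates ``0..i`` can
    have at ``x_i``.  Convexity propagates lower bounds forward along the
    steepest line through an earlier ceiling corner and a later floor
    corner, so ``A_i`` is the upper envelope of those extremal tangents
    (and the floor itself); the prefix is convex-feasible while
    ``A_i <= up_i``.  ``B_i`` is the mirrored largest height of a concave
    path through gates ``i..m-1``.  A unimodal path exists iff some split
    ``k`` has a feasible convex prefix, feasible concave suffix, and
    ``A_k <= B_{k+1}``.
    """
    m = len(xs)
    # steepest upward slope into each floor corner j from earlier ceilings
    A = np.empty(m)
    okL = np.empty(m, np.bool_)
    slope_in = np.full(m, -np.inf)
    for j in range(1, m):
        best = -np.inf
        for j1 in range(j):
            s = (lo[j] - up[j1]) / (xs[j] - xs[j1])
            if s > best:
                best = s
        slope_in[j] = best
    A[0] = lo[0]
    okL[0] = lo[0] <= up[0]
    for i in range(1, m):
        best = lo[i]
        for j in range(1, i):
            v = lo[j] + slope_in[j] * (xs[i] - xs[j])
            if v > best:
                best = v
        A[i] = best
        okL[i] = okL[i - 1] and best <= up[i]

    B = np.empty(m)
    okR = np.empty(m, np.bool_)
    # steepest upward slope demanded after each ceiling corner j by later floors
    slope_out = np.full(m, -np.inf)
    for j in range(1, m - 1):
        best = -np.inf
        for j4 in range(j + 1, m):
            s = (lo[j4] - up[j]) / (xs[j4] - xs[j])
            if s > best:
                best = s
        slope_out[j] = best
    B[m - 1] = up[m - 1]
    okR[m - 1] = lo[m - 1] <= up[m - 1]
    for i in range(m - 2, -1, -1):
        best = up[i]
        for j in range(i + 1, m - 1):
            v = up[j] - slope_out[j] * (xs[j] - xs[i])
            if v < best:
                best = v
        B[i] = best
        okR[i] = okR[i + 1] and best >= lo[i]

    if okR[0] or okL[m - 1]:  # purely concave or purely convex
        return True
    for k in range(m - 1):
        if okL[k] and okR[k + 1] and A[k] <= B[k + 1]:
            return True
    return False


def dip_statistic(values) -> float:
    """Hartigan's dip: sup-distance from the empirical CDF to the nearest
    unimodal CDF.  Requires >= 4 distinct values."""
    x, U, L = _step_corners(values)
    m = len(x)
    if m < 4:
        raise ValueError("need at least 4 distinct values")
    # t must at least half-cover the tallest CDF step (heaviest tie group)
    t_lo = 0.5 * float(np.max(L - U)) * (1.0 - 1e-12)
    t_hi = 0.26  # the dip never exceeds 1/4
    if not _unimodal_path_exists(x, L - t_hi, U + t_hi):  # pragma: no cover
        raise RuntimeError("taut-string sweep failed at the trivial bound")
    for _ in range(52):
        t = 0.5 * (t_lo + t_hi)
        if _unimodal_path_exists(x, L - t, U + t):
            t_hi = t
        else:
            t_lo = t
    return 0.5 * (t_lo + t_hi)


def excess_mass_stat(values) -> float:
    """Excess-mass statistic for one vs two modes (equals twice the dip)."""
    return 2.0 * dip_statistic(values)


# -------------------------------------------------------- calibration null


def _kde_density(x: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * h * np.sqrt(2 * np.pi))


def _n_modes(x: np.ndarray, h: float, grid: np.ndarray) -> int:
    d = _kde_density(x, h, grid)
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    return int(interior.sum())


def silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-1 / 5)


def critical_bandwidth(values, grid_size: int = 400, tol: float = 1e-4) -> float:
    """Smallest Gaussian-KDE bandwidth (relative tolerance) at which the
    density of ``values`` has a single mode."""
    x = np.asarray(values, dtype=float)
    h = max(silverman_bandwidth(x), 1e-12)
    span_pad = 4.0
    hi = h
    grid = np.linspace(x.min() - span_pad * hi, x.max() + span_pad * hi, grid_size)
    while _n_modes(x, hi, grid) > 1:
        hi *= 2.0
        grid = np.linspace(x.min() - span_pad * hi, x.max() + span_pad * hi, grid_size)
    lo = hi / 2.0
    while _n_modes(x, lo, grid) <= 1 and lo > 1e-9 * hi:
        hi = lo
        lo /= 2.0
    # bisect in [lo, hi]: lo multimodal (or negligible), hi unimodal
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _n_modes(x, mid, grid) <= 1:
            hi = mid
        else:
            lo = mid
        if (hi - lo) / hi < tol:
            break
    return float(hi)


def excess_mass_test(
    values,
    n_bootstrap: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Excess-mass test of unimodality.

    The null distribution of the statistic is simulated by a smoothed
    bootstrap from the unimodal Gaussian-KDE density of the data at its
    critical bandwidth, rescaled to preserve the sample variance; the
    p-value is ``(1 + #{stat* >= stat}) / (1 + n_bootstrap)``.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct values")
    if n_bootstrap < 19:
        raise ValueError("n_bootstrap must be >= 19")
    rng = rng or np.random.default_rng()
    stat = excess_mass_stat(x)
    h = critical_bandwidth(x)
    n = len(x)
    mean, var = float(np.mean(x)), float(np.var(x, ddof=1))
    shrink = 1.0 / np.sqrt(1.0 + h * h / var)
    exceed = 0
    for _ in range(n_bootstrap):
        y = x[rng.integers(0, n, size=n)] + h * rng.standard_normal(n)
        y = mean + (y - mean) * shrink
        if excess_mass_stat(y) >= stat:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_bootstrap)
    return stat, p


# ---------------------------------------------------------- KDE threshold


@dataclass(frozen=True)
class KDEThreshold:
    threshold: float | None  # ms; None when the density is unimodal
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    unimodal: bool


def kde_threshold(taus, grid_size: int = 512) -> KDEThreshold:
    """Global interior minimum of the Gaussian KDE between the two tallest
    modes of the timescale distribution (linear axis, Silverman bandwidth).

    Returns ``threshold=None`` with ``unimodal=True`` when the density has a
    single local maximum.
    """
    from scipy import stats

    x = np.asarray(taus, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 timescale values")
    if np.any(x <= 0):
        raise ValueError("timescales must be positive")
    # robust Silverman bandwidth (min of SD and IQR/1.349): a handful of
    # boundary-valued estimates must not oversmooth the density
    bw = silverman_bandwidth(x)
    kde = stats.gaussian_kde(x, bw_method=bw / np.std(x, ddof=1))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    d = kde(grid)
    interior = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    # tail ripples from isolated extreme values are not modes
    interior = interior[d[interior] >= 0.02 * d.max()]
    if len(interior) < 2:
        return KDEThreshold(None, bw, grid, d, unimodal=True)
    top_two = interior[np.argsort(d[interior])[-2:]]
    left, right = int(top_two.min()), int(top_two.max())
    between = slice(left, right + 1)
    thr_idx = left + int(np.argmin(d[between]))
    return KDEThreshold(float(grid[thr_idx]), bw, grid, d, unimodal=False)


def classify_by_threshold(taus, threshold: float) -> np.ndarray:
    """Label each timescale ``"short"`` (tau < threshold) or ``"long"``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    taus = np.asarray(taus, dtype=float)
    return np.where(taus < threshold, "short", "long")


@dataclass(frozen=True)
class ModalityResult:
    statistic: float
    p_value: float
    n_bootstrap: int
    threshold: float | None
    bandwidth: float
    labels: np.ndarray | None


def modality_analysis(
    taus,
    n_bootstrap: int = 500,
    rng: np.random.Generator | None = None,
) -> ModalityResult:
    """Excess-mass test plus KDE-threshold classification in one call."""
    stat, p = excess_mass_test(taus, n_bootstrap=n_bootstrap, rng=rng)
    kt = kde_threshold(taus)
    labels = None if kt.unimodal else classify_by_threshold(taus, kt.threshold)
    return ModalityResult(
        statistic=stat,
        p_value=p,
        n_bootstrap=n_bootstrap,
        threshold=kt.threshold,
        bandwidth=kt.bandwidth,
        labels=labels,
    )
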