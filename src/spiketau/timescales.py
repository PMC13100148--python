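"""Intrinsic-timescale estimation from baseline spike counts.

The estimator follows the standard spike-count autocorrelation procedure:
baseline spikes are binned (10 ms default), the across-trial mean of each bin
is subtracted, lagged products of the residuals are averaged over trials,
normalized by the zero-lag value, and the resulting autocorrelation profile
is fit with a single exponential decay

    f(lag) = A * (exp(-lag / tau) + B)

by bounded least squares (Trust Region Reflective).  Because refractoriness
can depress the first lags, the fit starts at the lag where the profile is
maximal (excluding lag zero).  Quality control keeps fits with pseudo-R^2
above a floor; precision is summarized by CV = SE(tau)/tau from the
least-squares covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import check_window
from .table import SpikeTable

DEFAULT_BIN_WIDTH = 10.0
DEFAULT_BASELINE_WINDOW = (200.0, 500.0)
DEFAULT_R2_MIN = 0.3
DEFAULT_BOUNDS = {"tau": (1.0, 500.0), "amplitude": (0.0, 10.0), "offset": (-1.0, 1.0)}


class DegenerateProfileError(ValueError):
    """Residual variance is zero: no autocorrelation profile exists."""


class UnfittableProfileError(ValueError):
    """The profile has no decaying segment (argmax at the final lag)."""


@dataclass(frozen=True)
class BinnedCounts:
    """Trials x bins spike-count matrix for one neuron and window."""

    counts: np.ndarray  # (n_trials, n_bins) nonnegative integers
    bin_width: float
    window: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class AutocorrProfile:
    lags: np.ndarray  # ms, multiples of bin_width, starting at 0
    coefficients: np.ndarray  # normalized so coefficients[0] == 1
    n_trials: int


@dataclass(frozen=True)
class TimescaleFit:
    tau: float
    amplitude: float
    offset: float
    fit_start_lag: float
    r_squared: float
    cv: float
    converged: bool
    message: str = ""


def bin_spikes(
    spike_times_per_trial,
    window: tuple[float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedCounts:
    """Bin per-trial spike times into half-open ``[start+j*w, start+(j+1)*w)`` bins."""
    lo, hi = check_window(window, bin_width)
    if len(spike_times_per_trial) == 0:
        raise ValueError("need at least one trial to bin")
    n_bins = int(round((hi - lo) / bin_width))
    rows = []
    for t in spike_times_per_trial:
        t = np.asarray(t, dtype=float)
        inside = t[(t >= lo) & (t < hi)]  # strictly half-open, unlike np.histogram
        idx = np.floor((inside - lo) / bin_width).astype(np.int64)
        idx = np.minimum(idx, n_bins - 1)  # guard float round-up at bin edges
        rows.append(np.bincount(idx, minlength=n_bins))
    return BinnedCounts(counts=np.stack(rows).astype(np.int64), bin_width=bin_width,
                        window=(lo, hi))


def compute_autocorrelation(binned: BinnedCounts) -> AutocorrProfile:
    """Trial-averaged, zero-lag-normalized autocorrelation of count residuals.

    Residuals remove the across-trial mean of each bin; the lag-k raw value is
    the per-trial mean of ``sum_i r_i r_{i+k} / (n_bins - k)`` averaged over
    trials, then scaled by the lag-0 value.
    """
    counts = binned.counts.astype(float)
    if binned.n_trials < 2 or binned.n_bins < 2:
        raise ValueError("need >= 2 trials and >= 2 bins")
    resid = counts - counts.mean(axis=0, keepdims=True)
    n_bins = binned.n_bins
    raw = np.empty(n_bins)
    for k in range(n_bins):
        prod = resid[:, : n_bins - k] * resid[:, k:]
        raw[k] = prod.sum(axis=1).mean() / (n_bins - k)
    if raw[0] <= 0:
        raise DegenerateProfileError("zero residual variance across all bins")
    return AutocorrProfile(
        lags=binned.bin_width * np.arange(n_bins),
        coefficients=raw / raw[0],
        n_trials=binned.n_trials,
    )


def _exp_model(x, tau, amplitude, offset):
    return amplitude * (np.exp(-x / tau) + offset)


def fit_timescale(
    profile: AutocorrProfile,
    bounds: dict | None = None,
    max_nfev: int = 10_000,
) -> TimescaleFit:
    """Fit ``A * (exp(-lag/tau) + B)`` to the profile from its peak lag onward."""
    bounds = bounds or DEFAULT_BOUNDS
    lags, coef = profile.lags, profile.coefficients
    if len(lags) < 2:
        raise ValueError("profile too short")
    start_idx = 1 + int(np.argmax(coef[1:]))  # ties break toward the smaller lag
    if start_idx == len(lags) - 1:
        raise UnfittableProfileError("autocorrelation peaks at the final lag; no decay to fit")
    x = lags[start_idx:]
    y = coef[start_idx:]
    if len(x) < 4:
        raise UnfittableProfileError("fewer than 4 lags at or after the fit-start lag")

    lo = [bounds["tau"][0], bounds["amplitude"][0], bounds["offset"][0]]
    hi = [bounds["tau"][1], bounds["amplitude"][1], bounds["offset"][1]]
    a0 = float(y[0])
    below = np.flatnonzero(y < a0 * np.exp(-1.0))
    tau0 = float(x[below[0]]) if len(below) else float(x[-1])
    b0 = float(np.mean(y[-3:]))
    p0 = np.clip([tau0, a0, b0], lo, hi)

    try:
        popt, pcov = optimize.curve_fit(
            _exp_model,
            x,
            y,
            p0=p0,
            bounds=(lo, hi),
            method="trf",
            max_nfev=max_nfev,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        converged, message = True, ""
    except RuntimeError as err:  # pragma: no cover - solver failure path
        return TimescaleFit(
            tau=float(p0[0]),
            amplitude=float(p0[1]),
            offset=float(p0[2]),
            fit_start_lag=float(x[0]),
            r_squared=-np.inf,
            cv=np.inf,
            converged=False,
            message=str(err),
        )
    resid = y - _exp_model(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    se_tau = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    return TimescaleFit(
        tau=float(popt[0]),
        amplitude=float(popt[1]),
        offset=float(popt[2]),
        fit_start_lag=float(x[0]),
        r_squared=r2,
        cv=se_tau / float(popt[0]),
        converged=converged,
        message=message,
    )


def qc_filter(
    fits: dict[int, TimescaleFit | None],
    r2_min: float = DEFAULT_R2_MIN,
) -> tuple[dict[int, TimescaleFit], dict[int, str]]:
    """Partition fits into kept (R^2 >= r2_min and converged) and excluded.

    ``None`` entries stand for profiles with no decaying segment and are
    excluded with reason ``"no-decay"``.
    """
    kept: dict[int, TimescaleFit] = {}
    excluded: dict[int, str] = {}
    for key, fit in fits.items():
        if fit is None:
            excluded[key] = "no-decay"
        elif not fit.converged:
            excluded[key] = "non-convergence"
        elif fit.r_squared < r2_min:
            excluded[key] = f"r_squared {fit.r_squared:.3f} < {r2_min}"
        else:
            kept[key] = fit
    return kept, excluded


def estimate_neuron_timescale(
    table: SpikeTable,
    neuron_id: int,
    condition: str | None = None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
    trial_ids=None,
) -> TimescaleFit | None:
    """Full per-neuron pipeline: bin -> autocorrelation -> exponential fit.

    Returns ``None`` when the profile has no decaying segment, and raises
    :class:`DegenerateProfileError` for constant counts.
    """
    if trial_ids is None:
        trial_ids = table.trials_for(neuron_id, condition=condition)["trial_id"].to_numpy()
    trains = table.spike_trains(neuron_id, trial_ids)
    binned = bin_spikes(trains, baseline_window, bin_width)
    profile = compute_autocorrelation(binned)
    try:
        return fit_timescale(profile)
    except UnfittableProfileError:
        return None


def estimate_timescales(
    table: SpikeTable,
    condition: str | None = None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r2_min: float = DEFAULT_R2_MIN,
    neuron_ids=None,
) -> pd.DataFrame:
    """Per-neuron timescale table with QC flags for one condition."""
    if neuron_ids is None:
        neuron_ids = table.neuron_ids()
    fits: dict[int, TimescaleFit | None] = {}
    degenerate: dict[int, str] = {}
    for nid in neuron_ids:
        try:
            fits[nid] = estimate_neuron_timescale(
                table, nid, condition, baseline_window, bin_width
            )
        except DegenerateProfileError:
            degenerate[int(nid)] = "degenerate-profile"
    kept, excluded = qc_filter(fits, r2_min)
    excluded.update(degenerate)
    rows = []
    for nid in neuron_ids:
        nid = int(nid)
        fit = fits.get(nid)
        rows.append(
            {
                "neuron_id": nid,
                "condition": condition if condition is not None else "all",
                "tau_ms": fit.tau if fit else np.nan,
                "amplitude": fit.amplitude if fit else np.nan,
                "offset": fit.offset if fit else np.nan,
                "fit_start_ms": fit.fit_start_lag if fit else np.nan,
                "r_squared": fit.r_squared if fit else np.nan,
                "cv": fit.cv if fit else np.nan,
                "kept": nid in kept,
                "exclusion_reason": excluded.get(nid, ""),
            }
        )
    return pd.DataFrame(rows)


def split_half_stability(
    table: SpikeTable,
    neuron_ids=None,
    condition: str | None = None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r2_min: float = DEFAULT_R2_MIN,
    min_trials_per_half: int = 20,
) -> tuple[pd.DataFrame, float, float]:
    """Estimate tau independently on the first and second half of each
    neuron's trials (temporal order) and return the per-neuron pairs plus
    Spearman's rank correlation between halves.

    Neurons with fewer than ``min_trials_per_half`` trials per half, or
    failing QC in either half, are dropped from the stability set.
    """
    if neuron_ids is None:
        neuron_ids = table.neuron_ids()
    rows = []
    for nid in neuron_ids:
        tids = np.sort(table.trials_for(nid, condition=condition)["trial_id"].to_numpy())
        half = len(tids) // 2
        if half < min_trials_per_half:
            continue
        taus = []
        for part in (tids[:half], tids[half:]):
            try:
                fit = estimate_neuron_timescale(
                    table, nid, condition, baseline_window, bin_width, trial_ids=part
                )
            except DegenerateProfileError:
                fit = None
            taus.append(fit)
        kept = all(f is not None and f.converged and f.r_squared >= r2_min for f in taus)
        if kept:
            rows.append(
                {"neuron_id": int(nid), "tau_first": taus[0].tau, "tau_second": taus[1].tau}
            )
    pairs = pd.DataFrame(rows, columns=["neuron_id", "tau_first", "tau_second"])
    if len(pairs) >= 3:
        rho, p = stats.spearmanr(pairs["tau_first"], pairs["tau_second"])
    else:
        rho, p = np.nan, np.nan
    return pairs, float(rho), float(p)


def baseline_descriptives(binned: BinnedCounts) -> dict[str, float]:
    """Baseline firing statistics for one neuron.

    rate
        total spikes / (n_trials * window length), spikes/s.
    temporal_cv
        SD across bins of the across-trial mean count, divided by their mean
        (population SD; scale-invariant measure of baseline dynamism).
    fano
        variance/mean of per-trial total counts (trial-to-trial variability).
    """
    counts = binned.counts.astype(float)
    if binned.n_trials < 2 or binned.n_bins < 2:
        raise ValueError("need >= 2 trials and >= 2 bins")
    window_s = (binned.window[1] - binned.window[0]) / 1000.0
    rate = counts.sum() / (binned.n_trials * window_s)
    bin_means = counts.mean(axis=0)
    overall = bin_means.mean()
    temporal_cv = float(bin_means.std(ddof=0) / overall) if overall > 0 else np.nan
    totals = counts.sum(axis=1)
    fano = float(totals.var(ddof=1) / totals.mean()) if totals.mean() > 0 else np.nan
    return {"rate": float(rate), "temporal_cv": temporal_cv, "fano": fano}
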