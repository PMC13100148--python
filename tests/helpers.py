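"""Independent oracles used by the test suite.

These deliberately re-derive quantities from their definitions (brute-force
loops, linear programming) rather than sharing any code path with the
package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def brute_force_autocorr(counts: np.ndarray) -> np.ndarray:
    """Trial-averaged lagged products of per-bin mean-subtracted counts,
    pair-count normalized and scaled by the zero-lag value — as an explicit
    triple loop."""
    counts = np.asarray(counts, dtype=float)
    n_trials, n_bins = counts.shape
    mean = counts.mean(axis=0)
    resid = counts - mean
    raw = []
    for k in range(n_bins):
        per_trial = []
        for t in range(n_trials):
            s = 0.0
            for i in range(n_bins - k):
                s += resid[t, i] * resid[t, i + k]
            per_trial.append(s / (n_bins - k))
        raw.append(sum(per_trial) / n_trials)
    return np.array(raw) / raw[0]


def lp_dip(values) -> float:
    """Dip statistic straight from its definition: for every candidate mode
    position, the least sup-deviation unimodal CDF fit is a linear program
    (monotone heights, convex left of the mode, concave right of it, within
    t of both corners of every empirical-CDF step); the dip is the smallest
    optimum.  O(n) LPs of size n — oracle-grade, not fast."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    distinct, first = np.unique(x, return_index=True)
    last = np.r_[first[1:], n] - 1
    U = first / n
    L = (last + 1) / n
    xs = distinct
    m = len(xs)
    best = np.inf
    for k in range(-1, m):
        c = np.zeros(m + 1)
        c[-1] = 1.0  # minimize t
        A_ub, b_ub = [], []
        for i in range(m):
            row = np.zeros(m + 1)
            row[i], row[-1] = -1.0, -1.0  # g_i >= L_i - t
            A_ub.append(row)
            b_ub.append(-L[i])
            row = np.zeros(m + 1)
            row[i], row[-1] = 1.0, -1.0  # g_i <= U_i + t
            A_ub.append(row)
            b_ub.append(U[i])
        for i in range(m - 1):  # monotone
            row = np.zeros(m + 1)
            row[i], row[i + 1] = 1.0, -1.0
            A_ub.append(row)
            b_ub.append(0.0)
        for i in range(1, m - 1):  # curvature by region
            dx0, dx1 = xs[i] - xs[i - 1], xs[i + 1] - xs[i]
            row = np.zeros(m + 1)
            row[i - 1] = 1.0 / dx0
            row[i] = -1.0 / dx1 - 1.0 / dx0
            row[i + 1] = 1.0 / dx1
            if i + 1 <= k:  # convex region
                A_ub.append(-row)
                b_ub.append(0.0)
            elif i - 1 >= k + 1:  # concave region
                A_ub.append(row)
                b_ub.append(0.0)
        res = linprog(
            c,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=[(0.0, 1.0)] * m + [(0.0, 1.0)],
            method="highs",
        )
        assert res.success, res.message
        best = min(best, res.fun)
    return float(best)
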