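"""Statistical linkage between timescales and function, plus group contrasts.

The central model is a robust multiple linear regression of per-neuron
intrinsic timescale on the four visual indices and baseline firing rate,

    tau_i = b0 + b1*SingleTransient_i + b2*SingleSustained_i
               + b3*PopoutTransient_i + b4*PopoutSustained_i
               + b5*FiringRate_i + eps_i,

fit by M-estimation with Huber weighting (tuning constant 1.345).  Because
regression residuals on neural data are rarely normal, coefficient p-values
come from a permutation scheme: the response is shuffled, the robust model
refit, and p is the (+1-corrected) fraction of permuted |beta| at least as
large as the observed one.  Multicollinearity is screened with variance
inflation factors.

Group contrasts use rank statistics (Wilcoxon signed-rank / rank-sum with
rank-biserial effect sizes), two-sample Cramer-von Mises by permutation,
chi-squared independence, Spearman association and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

HUBER_T = 1.345
DEFAULT_N_PERM = 10_000

PREDICTORS = [
    "single_transient",
    "single_sustained",
    "popout_transient",
    "popout_sustained",
    "firing_rate",
]


class CollinearityError(ValueError):
    """Design matrix is rank-deficient."""


@dataclass
class RegressionResult:
    params: pd.Series  # const + predictors
    bse: pd.Series
    resid: np.ndarray
    scale: float
    vif: pd.Series
    n_obs: int
    dropped: list = field(default_factory=list)  # listwise-deleted row labels
    perm_pvalues: pd.Series | None = None
    n_permutations: int = 0
    converged: bool = True
    residual_normality_p: float = float("nan")

    def added_variable_slope(self, predictor: str) -> float:
        """Added-variable (partial) slope of one predictor: the weighted OLS
        slope of response residuals on predictor residuals, both taken
        against the remaining predictors with the robust fit's weights."""
        X = self._design
        y = self._response
        w = self._weights
        others = [c for c in X.columns if c not in (predictor, "const")]
        Z = sm.add_constant(X[others]) if others else pd.DataFrame(
            {"const": np.ones(len(X))}, index=X.index
        )
        ry = y - sm.WLS(y, Z, weights=w).fit().fittedvalues
        rx = X[predictor] - sm.WLS(X[predictor], Z, weights=w).fit().fittedvalues
        return float(np.sum(w * rx * ry) / np.sum(w * rx * rx))


def _clean_design(design: pd.DataFrame, response: pd.Series):
    df = pd.concat([design, response.rename("__y__")], axis=1)
    ok = df.notna().all(axis=1)
    dropped = list(df.index[~ok])
    df = df[ok]
    return df.drop(columns="__y__"), df["__y__"], dropped


def _rlm_fit(X: np.ndarray, y: np.ndarray):
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T))
    return model.fit(conv="coefs", tol=1e-10, maxiter=300)


def fit_robust_regression(
    design: pd.DataFrame, response: pd.Series
) -> RegressionResult:
    """Huber M-estimated linear regression of ``response`` on ``design``.

    Rows with missing values are listwise-deleted (recorded in ``dropped``);
    a rank-deficient design raises :class:`CollinearityError` naming the
    dependent columns.
    """
    design, response, dropped = _clean_design(design, response)
    if len(design) <= design.shape[1] + 1:
        raise ValueError("need more observations than predictors")
    X = sm.add_constant(design)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = [
            c
            for c in design.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad}")
    fit = _rlm_fit(X.to_numpy(), response.to_numpy())
    params = pd.Series(fit.params, index=X.columns)
    bse = pd.Series(fit.bse, index=X.columns)
    resid = response.to_numpy() - X.to_numpy() @ fit.params
    normality_p = float(stats.shapiro(resid).pvalue) if len(resid) <= 5000 else float(
        stats.normaltest(resid).pvalue
    )
    result = RegressionResult(
        params=params,
        bse=bse,
        resid=resid,
        scale=float(fit.scale),
        vif=compute_vif(design) if design.shape[1] >= 2 else pd.Series(dtype=float),
        n_obs=len(design),
        dropped=dropped,
        residual_normality_p=normality_p,
    )
    result._design = X
    result._response = response
    result._weights = np.asarray(fit.weights, dtype=float)
    return result


def permutation_pvalues(
    design: pd.DataFrame,
    response: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-coefficient permutation p-values for the robust regression.

    The response is shuffled ``n_perm`` times with the design fixed and the
    robust model refit; ``p = (1 + #{|b*| >= |b|}) / (1 + n_perm)``.  A refit
    that fails to converge counts as an exceedance (conservative).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = rng or np.random.default_rng()
    design, response, _ = _clean_design(design, response)
    X = sm.add_constant(design).to_numpy()
    y = response.to_numpy()
    observed = np.abs(_rlm_fit(X, y).params)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        try:
            b = np.abs(_rlm_fit(X, y_perm).params)
            exceed += b >= observed
        except Exception:  # non-convergence counted against the null
            exceed += 1.0
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=["const"] + list(design.columns))


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: ``1 / (1 - R^2_j)`` from an
    OLS regression of predictor j on the remaining predictors."""
    if design.shape[1] < 2:
        raise ValueError("need >= 2 predictors for VIF")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col))
        r2 = sm.OLS(design[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ----------------------------------------------------------------- contrasts


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    effect_size: float
    n1: int
    n2: int


def _signed_rank_effect(d: np.ndarray) -> float:
    d = d[d != 0]
    if len(d) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return (w_pos - w_neg) / (w_pos + w_neg)


def _exact_ok(x, y):
    return max(len(x), len(y)) < 26


def _cvm_statistic(x, y) -> float:
    return float(stats.cramervonmises_2samp(x, y, method="asymptotic").statistic)


def cvm_permutation_test(
    x,
    y,
    n_perm: int = 9_999,
    rng: np.random.Generator | None = None,
    max_exact: int = 20_000,
) -> tuple[float, float]:
    """Two-sample Cramer-von Mises test with a permutation (or exhaustive,
    when the number of splits is small) null distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = rng or np.random.default_rng()
    observed = _cvm_statistic(x, y)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    if comb(n, n1) <= max_exact:
        exceed = total = 0
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            total += 1
            if _cvm_statistic(pooled[mask], pooled[~mask]) >= observed - 1e-12:
                exceed += 1
        return observed, exceed / total
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _cvm_statistic(pooled[perm[:n1]], pooled[perm[n1:]]) >= observed - 1e-12:
            exceed += 1
    return observed, (1.0 + exceed) / (1.0 + n_perm)


def compare_groups(
    x,
    y=None,
    test: str = "rank-sum",
    paired: bool = False,
    n_perm: int = 9_999,
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Two-group (or one-sample) comparison with effect size.

    tests: ``rank-sum`` (Mann-Whitney U, rank-biserial ``1 - 2U/(n1*n2)``),
    ``signed-rank`` (one-sample when ``y`` is None, paired otherwise;
    matched-pairs rank-biserial ``(W+ - W-)/(W+ + W-)``), ``cvm-two-sample``
    (permutation p), ``chi-squared`` (independence of two categorical
    vectors), ``spearman``.  Exact rank-test nulls are used below n = 26 per
    group (no ties), the continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x)
    if test == "rank-sum":
        y = np.asarray(y, dtype=float)
        xf = x.astype(float)
        if np.all(xf[:, None] == y[None, :]) and np.all(xf == xf[0]):
            warnings.warn("all values tied; p set to 1")
            return ComparisonResult(test, 0.0, 1.0, 0.0, len(x), len(y))
        ties = len(np.unique(np.concatenate([xf, y]))) < len(xf) + len(y)
        method = "exact" if (_exact_ok(xf, y) and not ties) else "asymptotic"
        res = stats.mannwhitneyu(xf, y, alternative="two-sided", method=method)
        effect = 1.0 - 2.0 * float(res.statistic) / (len(xf) * len(y))
        return ComparisonResult(test, float(res.statistic), float(res.pvalue),
                                effect, len(xf), len(y))
    if test == "signed-rank":
        xf = x.astype(float)
        d = xf - np.asarray(y, dtype=float) if (paired and y is not None) else xf
        if np.all(d == 0):
            warnings.warn("all differences zero; p set to 1")
            return ComparisonResult(test, 0.0, 1.0, 0.0, len(d), len(d))
        nz = d[d != 0]
        ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) < 26 and not ties) else "approx"
        res = stats.wilcoxon(d, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return ComparisonResult(test, float(res.statistic), float(res.pvalue),
                                _signed_rank_effect(d), len(d), len(d))
    if test == "cvm-two-sample":
        stat, p = cvm_permutation_test(x.astype(float), np.asarray(y, float),
                                       n_perm=n_perm, rng=rng)
        return ComparisonResult(test, stat, p, float("nan"), len(x), len(y))
    if test == "chi-squared":
        tbl = pd.crosstab(pd.Series(x), pd.Series(np.asarray(y)))
        chi2, p, dof, _ = stats.chi2_contingency(tbl, correction=False)
        n = tbl.to_numpy().sum()
        cramer_v = float(np.sqrt(chi2 / (n * (min(tbl.shape) - 1))))
        return ComparisonResult(test, float(chi2), float(p), cramer_v, len(x), len(x))
    if test == "spearman":
        rho, p = associate(x.astype(float), np.asarray(y, float))
        return ComparisonResult(test, rho, p, rho, len(x), len(x))
    raise ValueError(f"unknown test {test!r}")


def associate(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def indices_design(indices: pd.DataFrame, rates: pd.Series) -> pd.DataFrame:
    """Pivot a tidy index table into the regression design (one row per
    neuron: four indices plus baseline firing rate)."""
    wide = indices.pivot_table(
        index="neuron_id", columns=["stimulus_type", "period"], values="index"
    )
    design = pd.DataFrame(
        {
            "single_transient": wide[("single", "transient")],
            "single_sustained": wide[("single", "sustained")],
            "popout_transient": wide[("popout", "transient")],
            "popout_sustained": wide[("popout", "sustained")],
            "firing_rate": rates,
        }
    )
    return design
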