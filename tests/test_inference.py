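"""Robust regression, permutation inference, VIF, rank tests, CvM, FDR."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import spiketau as st
from spiketau.inference import CollinearityError, HUBER_T


def _design(rng, n=100, k=3):
    return pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])


class TestRobustRegression:
    def test_noiseless_data_fit_exactly(self, rng):
        X = _design(rng)
        beta = np.array([2.0, -1.0, 0.5])
        y = pd.Series(1.5 + X.to_numpy() @ beta)
        fit = st.fit_robust_regression(X, y)
        np.testing.assert_allclose(fit.params["const"], 1.5, atol=1e-6)
        np.testing.assert_allclose(fit.params[X.columns], beta, atol=1e-6)

    def test_matches_direct_huber_minimization(self, rng):
        """The IRLS solution minimizes the Huber objective: compare against a
        generic numerical optimizer at the IRLS scale estimate."""
        X = _design(rng, n=80)
        y = pd.Series(X["x0"].to_numpy() - 2 * X["x1"].to_numpy()
                      + rng.standard_t(df=3, size=80))
        fit = st.fit_robust_regression(X, y)
        Xc = np.c_[np.ones(80), X.to_numpy()]
        scale = fit.scale

        def huber_obj(beta):
            r = (y.to_numpy() - Xc @ beta) / scale
            small = np.abs(r) <= HUBER_T
            return float(
                np.sum(0.5 * r[small] ** 2)
                + np.sum(HUBER_T * (np.abs(r[~small]) - 0.5 * HUBER_T))
            )

        res = optimize.minimize(huber_obj, np.zeros(4), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        irls_beta = np.r_[fit.params["const"], fit.params[X.columns]]
        assert huber_obj(irls_beta) <= res.fun + 1e-6

    def test_robust_beats_ols_under_contamination(self, rng):
        """With 5% gross response outliers the Huber fit recovers the true
        coefficients better than OLS (median over seeds)."""
        import statsmodels.api as sm

        beta = np.array([1.0, -2.0])
        rob_err, ols_err = [], []
        for seed in range(40):
            r = np.random.default_rng(seed)
            X = _design(r, n=100, k=2)
            y = X.to_numpy() @ beta + r.normal(0, 0.5, 100)
            out = r.choice(100, size=5, replace=False)
            y[out] += r.choice([-1, 1], 5) * 40.0
            y = pd.Series(y)
            fit = st.fit_robust_regression(X, y)
            rob_err.append(np.linalg.norm(fit.params[X.columns] - beta))
            ols = sm.OLS(y, sm.add_constant(X)).fit()
            ols_err.append(np.linalg.norm(ols.params[X.columns] - beta))
        assert np.median(rob_err) < np.median(ols_err)

    def test_collinear_design_rejected(self, rng):
        X = _design(rng, k=2)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(CollinearityError, match="dup|x0"):
            st.fit_robust_regression(X, pd.Series(rng.normal(size=len(X))))

    def test_listwise_deletion_recorded(self, rng):
        X = _design(rng, n=50)
        X.iloc[3, 0] = np.nan
        y = pd.Series(rng.normal(size=50))
        fit = st.fit_robust_regression(X, y)
        assert fit.dropped == [3]
        assert fit.n_obs == 49

    def test_reduces_to_ols_without_large_residuals(self, rng):
        """All Huber weights are 1 when no scaled residual exceeds the
        tuning constant, so the fit equals OLS."""
        import statsmodels.api as sm

        X = _design(rng, n=60, k=2)
        noise = 0.1 * np.sin(np.arange(60))  # bounded, max/MAD well below 1.345
        y = pd.Series(X["x0"].to_numpy() + noise)
        fit = st.fit_robust_regression(X, y)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(),
                                   rtol=1e-4)


class TestPermutationPvalues:
    def test_minimum_p_and_default(self):
        import inspect

        assert inspect.signature(st.permutation_pvalues).parameters["n_perm"].default == 10_000
        rng = np.random.default_rng(0)
        X = _design(rng, n=40, k=2)
        y = pd.Series(X["x0"].to_numpy() * 5.0 + rng.normal(0, 0.1, 40))
        p = st.permutation_pvalues(X, y, n_perm=49, rng=rng)
        assert p["x0"] == pytest.approx(1.0 / 50.0)  # minimum attainable
        assert (p >= 1.0 / 50.0).all()

    def test_rejects_tiny_n_perm(self, rng):
        X = _design(rng, n=30, k=2)
        with pytest.raises(ValueError):
            st.permutation_pvalues(X, pd.Series(rng.normal(size=30)), n_perm=5, rng=rng)

    def test_null_calibration(self):
        """Under independence, per-coefficient rejection at alpha = 0.05 stays
        inside the exact binomial band (scaled replicate of acceptance)."""
        reps, alpha = 120, 0.05
        rejections = np.zeros(3)
        for seed in range(reps):
            r = np.random.default_rng(seed)
            X = _design(r, n=60, k=3)
            y = pd.Series(r.normal(size=60))
            p = st.permutation_pvalues(X, y, n_perm=79, rng=r)
            rejections += (p[X.columns] < alpha).to_numpy()
        lo, hi = stats.binom.interval(0.999, reps, alpha)
        assert all(lo <= rj <= hi for rj in rejections)


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        from scipy.linalg import hadamard

        X = pd.DataFrame(hadamard(8)[:, 1:4].astype(float), columns=list("abc"))
        vif = st.compute_vif(X)  # orthogonal zero-mean columns
        np.testing.assert_allclose(vif.to_numpy(), 1.0, atol=1e-10)

    def test_near_duplicate_predictor_flagged(self, rng):
        X = _design(rng, n=200, k=2)
        X["near"] = X["x0"] + rng.normal(0, 0.01, 200)
        assert st.compute_vif(X)["near"] > 10

    def test_scale_invariance(self, rng):
        X = _design(rng, n=100, k=3)
        v1 = st.compute_vif(X)
        X2 = X.copy()
        X2["x1"] = X2["x1"] * 1e4
        v2 = st.compute_vif(X2)
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), rtol=1e-8)

    def test_perfect_collinearity_infinite(self, rng):
        X = _design(rng, n=50, k=2)
        X["dup"] = 3.0 * X["x0"]
        assert np.isinf(st.compute_vif(X)["dup"])


class TestCompareGroups:
    def test_identical_samples_null_result(self, rng):
        x = rng.normal(size=20)
        res = st.compare_groups(x, x.copy(), test="rank-sum")
        assert abs(res.effect_size) < 1e-12
        assert res.p_value > 0.9

    def test_complete_separation_rank_biserial(self):
        res = st.compare_groups([1.0, 2.0, 3.0], [10.0, 20.0, 30.0], test="rank-sum")
        assert res.effect_size == pytest.approx(1.0)  # U = 0 -> r = 1
        assert res.p_value == pytest.approx(0.1)  # exact two-sided 2/C(6,3)

    def test_signed_rank_effect_size(self):
        x = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        y = x - 1.0
        res = st.compare_groups(x, y, test="signed-rank", paired=True)
        assert res.effect_size == pytest.approx(1.0)  # all positive differences
        res2 = st.compare_groups(y, x, test="signed-rank", paired=True)
        assert res2.effect_size == pytest.approx(-1.0)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = st.compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], test="rank-sum")
        assert res.p_value == 1.0

    def test_chi_squared_independence(self, rng):
        a = np.repeat(["u", "v"], 50)
        b = np.where(rng.random(100) < 0.5, "x", "y")
        res = st.compare_groups(a, b, test="chi-squared")
        assert res.p_value > 0.001  # independent labels: no association

    def test_cvm_exhaustive_matches_enumeration(self, rng):
        """At n1 = n2 = 4 the permutation p equals the exhaustive proportion
        over all 70 label assignments, recomputed here from scratch."""
        x = rng.normal(size=4)
        y = rng.normal(loc=1.0, size=4)
        stat, p = st.cvm_permutation_test(x, y)
        pooled = np.concatenate([x, y])
        count = total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            s = stats.cramervonmises_2samp(pooled[mask], pooled[~mask],
                                           method="asymptotic").statistic
            total += 1
            count += s >= stat - 1e-12
        assert p == pytest.approx(count / total)
        assert stat == pytest.approx(
            stats.cramervonmises_2samp(x, y, method="asymptotic").statistic
        )


class TestAssociateAndFDR:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert st.associate(x, x * 2 + 1)[0] == pytest.approx(1.0)
        assert st.associate(x, -x)[0] == pytest.approx(-1.0)

    def test_null_association_small(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            rho, _ = st.associate(r.uniform(size=1000), r.uniform(size=1000))
            hits += abs(rho) < 0.1
        assert hits >= 38

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = st.associate(np.ones(10), np.arange(10.0))
        assert np.isnan(rho)

    def test_fdr_step_up(self):
        np.testing.assert_allclose(st.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        assert st.fdr_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(st.fdr_adjust([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])
        monotone = st.fdr_adjust([0.001, 0.01, 0.02, 0.8])
        assert (np.diff(monotone) >= -1e-12).all()

    def test_fdr_rejects_invalid(self):
        with pytest.raises(ValueError):
            st.fdr_adjust([0.5, 1.2])
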