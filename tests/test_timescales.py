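"""Timescale estimation: binning, autocorrelation vs brute force,
exponential fitting, QC, stability, descriptives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import spiketau as st
from spiketau.timescales import (
    DegenerateProfileError,
    UnfittableProfileError,
    _exp_model,
)
from spiketau._utils import child_rng
from helpers import brute_force_autocorr


class TestBinSpikes:
    @pytest.mark.parametrize(
        "spikes, expected_bin0, expected_bin1",
        [
            ([200.0, 209.99], 2, 0),  # both inside the half-open first bin
            ([210.0], 0, 1),  # boundary spike belongs to the next bin
            ([199.999, 500.0], 0, 0),  # outside the window entirely
        ],
    )
    def test_half_open_binning(self, spikes, expected_bin0, expected_bin1):
        b = st.bin_spikes([np.array(spikes)], (200.0, 500.0), 10.0)
        assert b.n_bins == 30
        assert b.counts[0, 0] == expected_bin0
        assert b.counts[0, 1] == expected_bin1

    def test_window_must_be_multiple_of_bin_width(self):
        with pytest.raises(ValueError):
            st.bin_spikes([np.array([250.0])], (200.0, 505.0), 10.0)
        with pytest.raises(ValueError):
            st.bin_spikes([], (200.0, 500.0), 10.0)


class TestAutocorrelation:
    @given(
        hyp.integers(min_value=2, max_value=8),
        hyp.integers(min_value=3, max_value=10),
        hyp.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, n_trials, n_bins, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 6, size=(n_trials, n_bins))
        if np.allclose(counts - counts.mean(0), 0):
            return
        b = st.BinnedCounts(counts=counts, bin_width=10.0, window=(0.0, 10.0 * n_bins))
        prof = st.compute_autocorrelation(b)
        np.testing.assert_allclose(
            prof.coefficients, brute_force_autocorr(counts), atol=1e-12
        )
        assert prof.coefficients[0] == 1.0

    def test_trial_offsets_give_unit_coefficients(self):
        """Residuals constant within each trial are perfectly lag-correlated."""
        counts = np.outer([1, 3, 5], np.ones(6, dtype=int))
        b = st.BinnedCounts(counts=counts, bin_width=10.0, window=(0.0, 60.0))
        prof = st.compute_autocorrelation(b)
        np.testing.assert_allclose(prof.coefficients, 1.0)

    def test_independent_counts_have_zero_mean_lags(self, rng):
        counts = rng.poisson(2.0, size=(500, 30))
        b = st.BinnedCounts(counts=counts, bin_width=10.0, window=(0.0, 300.0))
        prof = st.compute_autocorrelation(b)
        tail = prof.coefficients[1:]
        assert abs(tail.mean()) < 3 * tail.std(ddof=1) / np.sqrt(len(tail))

    def test_constant_counts_degenerate(self):
        counts = np.full((5, 10), 3, dtype=int)
        b = st.BinnedCounts(counts=counts, bin_width=10.0, window=(0.0, 100.0))
        with pytest.raises(DegenerateProfileError):
            st.compute_autocorrelation(b)


class TestFitTimescale:
    @pytest.mark.parametrize("tau", [10.0, 25.0, 50.0, 100.0, 300.0])
    def test_noiseless_recovery(self, tau):
        lags = np.arange(0, 300.0, 10.0)
        coef = _exp_model(lags, tau, 0.8, 0.1)
        coef[0] = 1.0
        fit = st.fit_timescale(st.AutocorrProfile(lags=lags, coefficients=coef, n_trials=100))
        assert abs(fit.tau - tau) / tau < 1e-4
        assert abs(fit.amplitude - 0.8) / 0.8 < 1e-4
        assert abs(fit.offset - 0.1) / 0.1 < 1e-4
        assert fit.r_squared >= 0.999999

    def test_fit_starts_at_post_dip_peak(self):
        """A refractory dip at the first lag moves the fit start to the peak."""
        lags = np.arange(0, 200.0, 10.0)
        coef = _exp_model(lags, 40.0, 0.6, 0.05)
        coef[0] = 1.0
        coef[1] = 0.2  # depressed first lag
        shifted = coef.copy()
        shifted[2] = 0.6  # clear peak at 20 ms
        fit = st.fit_timescale(
            st.AutocorrProfile(lags=lags, coefficients=shifted, n_trials=50)
        )
        assert fit.fit_start_lag == 20.0

    def test_solver_beats_grid_search(self, rng):
        """The TRF solution is at least as good as a dense grid search."""
        lags = np.arange(10.0, 300.0, 10.0)
        truth = _exp_model(lags, 60.0, 0.7, 0.08)
        noisy = truth + rng.normal(0, 0.02, size=len(lags))
        prof = st.AutocorrProfile(
            lags=np.r_[0.0, lags], coefficients=np.r_[1.0, noisy], n_trials=100
        )
        fit = st.fit_timescale(prof)

        def sse(tau, a, b):
            return float(np.sum((noisy - _exp_model(lags, tau, a, b)) ** 2))

        grid_best = min(
            sse(tau, a, b)
            for tau in np.linspace(5, 300, 60)
            for a in np.linspace(0.3, 1.2, 19)
            for b in np.linspace(-0.2, 0.3, 26)
        )
        assert sse(fit.tau, fit.amplitude, fit.offset) <= grid_best + 1e-6

    def test_no_decay_unfittable(self):
        lags = np.arange(0, 100.0, 10.0)
        coef = np.linspace(1.0, 2.0, 10)  # monotonically increasing: peak at final lag
        coef[0] = 1.0
        with pytest.raises(UnfittableProfileError):
            st.fit_timescale(st.AutocorrProfile(lags=lags, coefficients=coef, n_trials=10))


class TestQCFilter:
    def test_threshold_boundary(self):
        def fake(r2):
            return st.TimescaleFit(tau=50.0, amplitude=0.5, offset=0.0,
                                   fit_start_lag=10.0, r_squared=r2, cv=0.1,
                                   converged=True)

        kept, excluded = st.qc_filter({1: fake(0.29), 2: fake(0.30), 3: None})
        assert set(kept) == {2}  # 0.30 kept (inclusive), 0.29 excluded
        assert "r_squared" in excluded[1]
        assert excluded[3] == "no-decay"

    def test_non_convergence_excluded(self):
        bad = st.TimescaleFit(tau=50.0, amplitude=0.5, offset=0.0, fit_start_lag=10.0,
                              r_squared=0.9, cv=0.1, converged=False)
        kept, excluded = st.qc_filter({1: bad})
        assert not kept and excluded[1] == "non-convergence"


class TestRecovery:
    def test_two_class_monotone_recovery(self):
        """Median estimated tau increases with true tau across a grid, and is
        within 20% for the well-sampled cases (seeded; scaled-down sweep)."""
        medians = {}
        for true_tau in (25.0, 50.0, 100.0, 150.0):
            est = []
            for i in range(25):
                rng = child_rng(7, int(true_tau), i)
                trains = st.simulate_baseline_epochs(true_tau, 15.0, 0.8, 400, 300.0, rng)
                b = st.bin_spikes(trains, (0.0, 300.0), 10.0)
                try:
                    fit = st.fit_timescale(st.compute_autocorrelation(b))
                except UnfittableProfileError:
                    continue
                if fit.converged and fit.r_squared >= 0.3:
                    est.append(fit.tau)
            medians[true_tau] = float(np.median(est))
        taus = sorted(medians)
        assert all(medians[a] < medians[b] for a, b in zip(taus, taus[1:]))
        assert abs(medians[25.0] - 25.0) / 25.0 < 0.20


class TestSplitHalf:
    @staticmethod
    def _session_table(taus, n_epochs, seed):
        import pandas as pd

        trial_rows, spike_rows = [], []
        tid = 0
        for nid, tau in enumerate(taus):
            trains = st.simulate_baseline_epochs(tau, 15.0, 1.0, n_epochs, 300.0,
                                                 child_rng(seed, nid))
            for tr in trains:
                trial_rows.append(
                    dict(trial_id=tid, neuron_id=nid, condition="control",
                         stimulus_type="single", stimulus_location=1,
                         fixation_on=0.0, stimulus_on=300.0, stimulus_off=800.0,
                         trial_end=800.0)
                )
                for t in tr:
                    spike_rows.append(dict(neuron_id=nid, trial_id=tid, spike_time_ms=t))
                tid += 1
        return st.SpikeTable(
            neurons=pd.DataFrame(
                dict(neuron_id=range(len(taus)), unit_type="multi", depth_um=0.0,
                     session_id=0)
            ),
            trials=pd.DataFrame(trial_rows),
            spikes=pd.DataFrame(spike_rows),
        )

    def test_identical_halves_perfectly_correlated(self):
        """Sessions whose two halves repeat the same trials give rho = 1."""
        import pandas as pd

        taus = 10.0 + 20.0 * np.arange(8)
        base = self._session_table(taus, 100, seed=1)
        # duplicate each neuron's trials as a second identical half
        trials2 = base.trials.copy()
        trials2["trial_id"] += base.trials["trial_id"].max() + 1
        spikes2 = base.spikes.copy()
        spikes2["trial_id"] += base.trials["trial_id"].max() + 1
        table = st.SpikeTable(
            neurons=base.neurons,
            trials=pd.concat([base.trials, trials2], ignore_index=True),
            spikes=pd.concat([base.spikes, spikes2], ignore_index=True),
        )
        pairs, rho, _ = st.split_half_stability(
            table, baseline_window=(0.0, 300.0), min_trials_per_half=50
        )
        assert len(pairs) >= 5
        np.testing.assert_allclose(pairs["tau_first"], pairs["tau_second"])
        assert rho == 1.0

    def test_reversed_ranks_give_negative_rho(self):
        """Spearman rho of exactly reversed tau ranks is -1 (sanity of the
        correlation convention on a constructed pair set)."""
        from scipy import stats

        first = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        second = first[::-1]
        rho, _ = stats.spearmanr(first, second)
        assert rho == pytest.approx(-1.0)

    def test_experiment_shaped_sessions_are_stable(self):
        """With two timescale classes and recording-length sessions (960
        trials), tau estimates from the two halves rank-correlate > 0.5."""
        from spiketau.synth import _draw_truncated_taus

        rng = child_rng(33, 999)
        taus = np.r_[
            _draw_truncated_taus(27.34, 16.5, 5.0, 25, rng),
            _draw_truncated_taus(102.64, 23.31, 5.0, 25, rng),
        ]
        table = self._session_table(taus, 960, seed=33)
        pairs, rho, p = st.split_half_stability(table, baseline_window=(0.0, 300.0))
        assert len(pairs) >= 30
        assert rho > 0.5
        assert p < 1e-3


class TestBaselineDescriptives:
    def _binned(self, counts):
        counts = np.asarray(counts)
        return st.BinnedCounts(counts=counts, bin_width=10.0,
                               window=(0.0, 10.0 * counts.shape[1]))

    def test_constant_counts_zero_temporal_cv(self):
        d = st.baseline_descriptives(self._binned(np.full((4, 6), 2)))
        assert d["temporal_cv"] == 0.0
        assert d["fano"] == 0.0
        assert d["rate"] == pytest.approx(200.0)  # 12 spikes per 60 ms trial

    def test_temporal_cv_scale_invariant(self, rng):
        counts = rng.poisson(3.0, size=(20, 12))
        a = st.baseline_descriptives(self._binned(counts))
        b = st.baseline_descriptives(self._binned(2 * counts))
        assert a["temporal_cv"] == pytest.approx(b["temporal_cv"])

    def test_poisson_fano_near_one(self, rng):
        counts = rng.poisson(2.0, size=(2000, 10))
        d = st.baseline_descriptives(self._binned(counts))
        mean_total = 20.0
        se = np.sqrt(2.0 / 2000)  # var of variance/mean ratio ~ 2/n for Poisson
        assert abs(d["fano"] - 1.0) < 3 * se
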