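"""Baseline estimation: pooled moments, PSD repair, GP mean/cov/band."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from begp import (
    DayRecord,
    ModelConfig,
    baseline_band,
    baseline_cov,
    baseline_mean,
    build_basis,
    estimate_baseline,
    evaluate_basis,
    load_baseline,
    psd_repair,
    save_baseline,
)
from begp.baseline import InsufficientDataError
from begp.basis import InvalidConfigurationError

from conftest import make_model_days


def _noiseless_days(basis, coef, n_days=3, n_obs=100, seed=0):
    rng = np.random.default_rng(seed)
    days = []
    for i in range(n_days):
        t = np.sort(rng.uniform(0, 24, size=n_obs))
        y = evaluate_basis(basis, t).matrix.T @ coef
        days.append(DayRecord(i + 1, t, y))
    return days


class TestPsdRepair:
    def test_identity_unchanged(self):
        np.testing.assert_array_equal(psd_repair(np.eye(3)), np.eye(3))

    def test_clips_negative_eigenvalue(self):
        out = psd_repair(np.diag([1.0, -0.5]))
        np.testing.assert_allclose(out, np.diag([1.0, 0.0]), atol=1e-14)

    def test_matches_independent_eigendecomposition_oracle(self):
        rng = np.random.default_rng(77)
        a = rng.normal(size=(5, 5))
        sym = (a + a.T) / 2
        # oracle via scipy's eigendecomposition, coded independently
        w, v = scipy.linalg.eigh(sym)
        expected = v @ np.diag(np.clip(w, 0, None)) @ v.T
        np.testing.assert_allclose(psd_repair(sym), expected, atol=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_output_psd_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 4))
        out = psd_repair(a)
        assert np.linalg.eigvalsh(out).min() >= -1e-12
        np.testing.assert_allclose(psd_repair(out), out, atol=1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            psd_repair(np.array([[1.0, np.nan], [np.nan, 1.0]]))


class TestEstimateBaseline:
    def test_identical_noiseless_days(self, basis13):
        rng = np.random.default_rng(1)
        coef = rng.normal(70, 5, size=13)
        days = _noiseless_days(basis13, coef, n_days=4)
        bl = estimate_baseline(days, basis13)
        np.testing.assert_allclose(bl.coef_mean, coef, atol=1e-6)
        np.testing.assert_allclose(bl.sample_cov, 0.0, atol=1e-8)
        np.testing.assert_allclose(bl.coef_cov, 0.0, atol=1e-8)
        assert bl.n_days == 4

    def test_two_day_constant_basis_sample_variance(self, const_basis):
        t = np.linspace(1, 23, 10)
        days = [
            DayRecord(1, t, np.full(10, 60.0)),
            DayRecord(2, t, np.full(10, 80.0)),
        ]
        cfg = ModelConfig(n_basis=1, spline_order=1, min_obs_per_day=3)
        bl = estimate_baseline(days, const_basis, cfg)
        # sample variance of {60, 80} with divisor M-1 = 200
        assert bl.sample_cov[0, 0] == pytest.approx(200.0)
        np.testing.assert_allclose(bl.coef_mean, [70.0])

    def test_insufficient_days_raise(self, basis13):
        days = _noiseless_days(basis13, np.full(13, 70.0), n_days=1)
        with pytest.raises(InsufficientDataError):
            estimate_baseline(days, basis13)

    def test_short_days_are_excluded_with_reason(self, basis13):
        rng = np.random.default_rng(2)
        coef = rng.normal(70, 5, size=13)
        days = _noiseless_days(basis13, coef, n_days=3, n_obs=100)
        days.append(DayRecord(9, np.array([5.0, 6.0]), np.array([70.0, 71.0])))
        bl = estimate_baseline(days, basis13)
        assert bl.n_days == 3
        assert [d for d, _ in bl.excluded_days] == [9]

    def test_covariance_estimator_is_unbiased(self, basis5):
        """The debiased coefficient covariance recovers the generating
        covariance in Monte-Carlo mean (within 3 standard errors)."""
        rng = np.random.default_rng(42)
        c_true = np.array([60.0, 75.0, 85.0, 70.0, 62.0])
        sigma_true = 4.0 * np.exp(
            -0.5 * ((np.arange(5)[:, None] - np.arange(5)) / 1.5) ** 2
        )
        reps = 120
        raws = np.empty((reps, 5, 5))
        for r in range(reps):
            days = make_model_days(basis5, 25, 80, c_true, sigma_true, 4.0, rng)
            raws[r] = estimate_baseline(days, basis5).coef_cov_raw
        mc_mean = raws.mean(axis=0)
        mc_se = raws.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mc_mean - sigma_true) <= 3 * mc_se)


class TestGPFunctions:
    def test_constant_mean(self, const_basis):
        days = [
            DayRecord(1, np.linspace(1, 23, 10), np.full(10, 68.0)),
            DayRecord(2, np.linspace(1, 23, 10), np.full(10, 72.0)),
        ]
        cfg = ModelConfig(n_basis=1, spline_order=1, min_obs_per_day=3)
        bl = estimate_baseline(days, const_basis, cfg)
        np.testing.assert_allclose(
            baseline_mean(bl, np.linspace(0, 24, 7)), 70.0
        )

    def test_mean_matches_direct_summation_oracle(self, fitted_baseline):
        grid = np.linspace(0.5, 23.5, 17)
        phi = evaluate_basis(fitted_baseline.basis, grid).matrix
        expected = np.array(
            [
                sum(
                    fitted_baseline.coef_mean[p] * phi[p, g]
                    for p in range(fitted_baseline.n_basis)
                )
                for g in range(grid.size)
            ]
        )
        np.testing.assert_allclose(
            baseline_mean(fitted_baseline, grid), expected, atol=1e-12
        )

    def test_cov_matches_double_loop_oracle(self, fitted_baseline):
        rng = np.random.default_rng(8)
        bl = fitted_baseline
        for _ in range(20):
            t, tau = rng.uniform(0, 24, size=2)
            phi_t = evaluate_basis(bl.basis, np.array([t])).matrix[:, 0]
            phi_tau = evaluate_basis(bl.basis, np.array([tau])).matrix[:, 0]
            expected = sum(
                phi_t[p] * bl.coef_cov[p, q] * phi_tau[q]
                for p in range(bl.n_basis)
                for q in range(bl.n_basis)
            )
            assert baseline_cov(bl, t, tau) == pytest.approx(expected, abs=1e-12)
            assert baseline_cov(bl, t, tau) == baseline_cov(bl, tau, t)

    def test_variance_nonnegative_and_continuous(self, fitted_baseline):
        grid = np.linspace(0, 24, 1441)
        band = baseline_band(fitted_baseline, grid)
        assert np.all(band.sd >= 0)
        # variance curve has no jumps beyond the basis resolution
        assert np.max(np.abs(np.diff(band.sd**2))) < 1.0

    def test_band_hand_computation(self, const_basis):
        # constant basis, mean 70, variance 4, k=3 -> [64, 76]
        from begp.baseline import HRBaseline

        bl = HRBaseline(
            coef_mean=np.array([70.0]),
            coef_cov=np.array([[4.0]]),
            coef_cov_raw=np.array([[4.0]]),
            sample_cov=np.array([[4.0]]),
            noise_var=1.0,
            n_days=5,
            basis=const_basis,
        )
        band = baseline_band(bl, np.linspace(0, 24, 5), k_sigma=3)
        np.testing.assert_allclose(band.lower3, 64.0)
        np.testing.assert_allclose(band.upper3, 76.0)

    def test_zero_multiplier_collapses_band(self, fitted_baseline):
        band = baseline_band(fitted_baseline, np.linspace(0, 24, 9), k_sigma=0)
        np.testing.assert_array_equal(band.lower3, band.mean)
        np.testing.assert_array_equal(band.upper3, band.mean)

    def test_negative_multiplier_rejected(self, fitted_baseline):
        with pytest.raises(InvalidConfigurationError):
            baseline_band(fitted_baseline, np.array([12.0]), k_sigma=-1)

    def test_include_noise_widens_band(self, fitted_baseline):
        grid = np.linspace(0, 24, 25)
        narrow = baseline_band(fitted_baseline, grid, include_noise=False)
        wide = baseline_band(fitted_baseline, grid, include_noise=True)
        assert np.all(wide.sd >= narrow.sd)

    def test_repair_never_raises_top_eigenvalue(self, fitted_baseline):
        raw_sym = (
            fitted_baseline.coef_cov_raw + fitted_baseline.coef_cov_raw.T
        ) / 2
        assert (
            np.linalg.eigvalsh(fitted_baseline.coef_cov).max()
            <= np.linalg.eigvalsh(raw_sym).max() + 1e-10
        )


class TestParameterRecovery:
    def test_errors_shrink_with_more_days(self, basis5):
        """Both pooled-moment errors decrease, on average, as the number of
        days grows — the baseline is consistent under its own model."""
        c_true = np.array([60.0, 75.0, 85.0, 70.0, 62.0])
        sigma_true = 4.0 * np.exp(
            -0.5 * ((np.arange(5)[:, None] - np.arange(5)) / 1.5) ** 2
        )
        mean_err, cov_err = [], []
        rng = np.random.default_rng(7)
        for m in (10, 50, 200):
            me, ce = 0.0, 0.0
            reps = 30
            for _ in range(reps):
                days = make_model_days(basis5, m, 60, c_true, sigma_true, 4.0, rng)
                bl = estimate_baseline(days, basis5)
                me += np.max(np.abs(bl.coef_mean - c_true))
                ce += np.max(np.abs(bl.coef_cov - sigma_true))
            mean_err.append(me / reps)
            cov_err.append(ce / reps)
        assert mean_err[0] > mean_err[1] > mean_err[2]
        assert cov_err[0] > cov_err[1] > cov_err[2]


def test_serialization_round_trip(tmp_path, fitted_baseline):
    path = tmp_path / "baseline.json"
    save_baseline(fitted_baseline, path)
    loaded = load_baseline(path)
    np.testing.assert_array_equal(loaded.coef_mean, fitted_baseline.coef_mean)
    np.testing.assert_array_equal(loaded.coef_cov, fitted_baseline.coef_cov)
    np.testing.assert_array_equal(loaded.basis.knots, fitted_baseline.basis.knots)
    assert loaded.noise_var == fitted_baseline.noise_var
    assert loaded.n_days == fitted_baseline.n_days
    assert loaded.excluded_days == fitted_baseline.excluded_days
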