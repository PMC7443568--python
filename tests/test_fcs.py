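"""Multiple-tau correlator, FCS model fits, diffusion-law statistics."""

import numpy as np
import pytest

from topofcs import CorrelationCurve, alpha_tau_correlation, autocorrelate, fit_alpha, fit_single_spot, tau_half
from topofcs.fcs import _model


def direct_autocorrelation(x, ks):
    """Brute-force O(n*tau) oracle with the same symmetric normalization."""
    out = []
    for k in ks:
        a, b = x[: len(x) - k], x[k:]
        out.append(np.mean(a * b) / (np.mean(a) * np.mean(b)) - 1.0)
    return np.array(out)


def bin_pairwise(x):
    n = len(x) - (len(x) % 2)
    return 0.5 * (x[0:n:2] + x[1:n:2])


class TestAutocorrelate:
    def test_constant_trace_zero_everywhere(self):
        curve = autocorrelate(np.full(256, 3.0))
        np.testing.assert_allclose(curve.G, 0.0, atol=1e-12)

    def test_iid_noise_near_zero(self, rng):
        x = rng.uniform(0.5, 1.5, 4096)
        curve = autocorrelate(x)
        assert np.all(np.abs(curve.G) < 3.0 / np.sqrt(len(x)))

    def test_first_block_equals_direct_estimator(self, rng):
        """First m lags must match the brute-force direct estimator exactly."""
        x = rng.exponential(1.0, 1000)
        curve = autocorrelate(x, m=16)
        expected = direct_autocorrelation(x, range(1, 17))
        np.testing.assert_allclose(curve.G[:16], expected, rtol=1e-12)

    def test_coarse_blocks_equal_direct_estimator_on_binned_trace(self, rng):
        x = rng.exponential(1.0, 2048)
        curve = autocorrelate(x, m=16)
        # level 1: lags 18..32 step 2 on the pairwise-binned trace
        binned = bin_pairwise(x)
        expected = direct_autocorrelation(binned, range(9, 17))
        np.testing.assert_allclose(curve.G[16:24], expected, rtol=1e-12)
        # level 2
        binned2 = bin_pairwise(binned)
        expected2 = direct_autocorrelation(binned2, range(9, 17))
        np.testing.assert_allclose(curve.G[24:32], expected2, rtol=1e-12)

    def test_lags_strictly_increasing_with_doubling(self, rng):
        curve = autocorrelate(rng.uniform(1, 2, 1024), m=8)
        assert np.all(np.diff(curve.lags) > 0)
        assert list(curve.lags[:8]) == list(range(1, 9))
        assert list(curve.lags[8:12]) == [10, 12, 14, 16]

    def test_zero_mean_trace_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            autocorrelate(np.zeros(256))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            autocorrelate(np.ones(32), m=16)


def synthetic_curve(N=10.0, tau_d=0.5, lags=None):
    if lags is None:
        lags = np.unique(np.concatenate([np.arange(1, 17), np.geomspace(18, 4096, 40).astype(int)])).astype(float)
    return CorrelationCurve(lags, _model(lags, 1.0 / N, tau_d), mean_intensity=1.0)


class TestFitSingleSpot:
    def test_exact_model_recovered_to_six_digits(self):
        fit = fit_single_spot(synthetic_curve(N=10.0, tau_d=0.5))
        assert fit.ok
        assert fit.N == pytest.approx(10.0, rel=1e-6)
        assert fit.tau_D == pytest.approx(0.5, rel=1e-6)

    def test_amplitude_is_inverse_occupancy(self):
        fit = fit_single_spot(synthetic_curve(N=4.0, tau_d=30.0))
        assert fit.amplitude == pytest.approx(0.25, rel=1e-6)

    def test_non_decaying_curve_flagged_not_garbage(self):
        lags = np.arange(1.0, 40.0)
        curve = CorrelationCurve(lags, np.full(39, -0.01), mean_intensity=1.0)
        fit = fit_single_spot(curve)
        assert not fit.ok and np.isnan(fit.tau_D)

    def test_intensity_rescaling_invariance(self, rng):
        """G is normalized, so scaling the trace leaves the fit unchanged."""
        x = np.abs(np.cumsum(rng.normal(0, 1, 2048))) + 5.0
        f1 = fit_single_spot(autocorrelate(x))
        f2 = fit_single_spot(autocorrelate(7.3 * x))
        # identical up to float rounding in the normalization, amplified by
        # the fit's conditioning
        assert f1.tau_D == pytest.approx(f2.tau_D, rel=1e-6)

    def test_noisy_curve_recovery_within_5pct_rmse(self, rng):
        """1% additive noise: tauD recovered within 5% RMSE over 100 draws."""
        base = synthetic_curve(N=5.0, tau_d=40.0)
        errs = []
        for _ in range(100):
            noisy = CorrelationCurve(
                base.lags, base.G + rng.normal(0, 0.01 * base.G[0], base.G.size), 1.0
            )
            fit = fit_single_spot(noisy)
            errs.append(fit.tau_D / 40.0 - 1.0)
        assert np.sqrt(np.mean(np.array(errs) ** 2)) < 0.05


class TestTauHalf:
    def test_equals_tau_d_for_exact_model(self):
        lags = np.geomspace(0.01, 100, 400)
        curve = synthetic_curve(N=2.0, tau_d=7.0, lags=lags)
        assert tau_half(curve) == pytest.approx(7.0, rel=0.01)

    def test_amplitude_scale_invariance(self):
        lags = np.geomspace(0.01, 100, 400)
        a = synthetic_curve(N=2.0, tau_d=7.0, lags=lags)
        b = CorrelationCurve(lags, 2.0 * a.G, 1.0)
        assert tau_half(a) == pytest.approx(tau_half(b), rel=1e-9)

    def test_two_component_curve_matches_root_finder(self):
        from scipy.optimize import brentq

        lags = np.geomspace(0.001, 1000, 2000)
        g = 0.5 / (1 + lags / 0.1) + 0.5 / (1 + lags / 10.0)
        curve = CorrelationCurve(lags, g, 1.0)
        th = tau_half(curve)
        f = lambda t: 0.5 / (1 + t / 0.1) + 0.5 / (1 + t / 10.0) - g[0] / 2.0
        exact = brentq(f, 0.001, 1000)
        assert 0.1 < th < 10.0
        assert th == pytest.approx(exact, rel=0.01)

    def test_never_crossing_returns_missing(self):
        curve = CorrelationCurve(np.arange(1.0, 20.0), np.full(19, 0.5), 1.0)
        assert tau_half(curve) is None


class TestFitAlpha:
    def test_exact_power_law_recovered(self):
        s = np.array([0.1, 0.25, 0.5, 1.0, 2.25])
        tau = 3.0 * s**0.5
        A, alpha, _, _ = fit_alpha(s, tau, np.full(5, 1e-6))
        assert alpha == pytest.approx(0.5, abs=1e-4)
        assert A == pytest.approx(3.0, rel=1e-3)

    def test_equal_weights_match_loglog_regression(self):
        s = np.array([0.25, 0.5, 1.0, 2.0])
        tau = 2.0 * s**0.8
        A, alpha, _, _ = fit_alpha(s, tau, tau**2 * 0.01)  # equal relative errors
        slope, intercept = np.polyfit(np.log(s), np.log(tau), 1)
        assert alpha == pytest.approx(slope, abs=1e-6)

    def test_weighting_matches_grid_search_oracle(self, rng):
        s = np.array([0.1, 0.25, 0.5, 1.0, 2.25])
        tau = 5.0 * s**0.6 * np.exp(rng.normal(0, 0.05, 5))
        var = (0.1 * tau) ** 2 * rng.uniform(0.5, 2.0, 5)
        A, alpha, _, _ = fit_alpha(s, tau, var)
        w = tau / var
        obj = lambda A_, al_: np.sum(w * (tau - A_ * s**al_) ** 2)
        # coarse grid + local polish around the reported optimum
        grid = [(a_, al_) for a_ in np.linspace(A * 0.8, A * 1.2, 81) for al_ in np.linspace(alpha - 0.2, alpha + 0.2, 81)]
        best = min(grid, key=lambda p: obj(*p))
        assert obj(A, alpha) <= obj(*best) + 1e-9

    def test_scale_equivariance(self):
        s = np.array([0.1, 0.5, 1.0, 2.0])
        tau = 1.7 * s**0.9
        var = (0.05 * tau) ** 2
        A1, a1, _, _ = fit_alpha(s, tau, var)
        A2, a2, _, _ = fit_alpha(s, 2 * tau, 4 * var)
        assert a2 == pytest.approx(a1, rel=1e-9)
        assert A2 == pytest.approx(2 * A1, rel=1e-9)

    def test_zero_variance_falls_back_unweighted(self, caplog):
        import logging

        s = np.array([0.5, 1.0, 2.0])
        tau = 2.0 * s
        with caplog.at_level(logging.WARNING, logger="topofcs.fcs"):
            _, alpha, _, _ = fit_alpha(s, tau, np.array([0.0, 1.0, 1.0]))
        assert alpha == pytest.approx(1.0, abs=1e-6)
        assert any("unweighted" in r.message for r in caplog.records)


class TestAlphaTauCorrelation:
    def test_perfect_anticorrelation(self):
        tau = np.array([1.0, 2.0, 3.0, 4.0])
        alpha = 5.0 - tau
        r, p = alpha_tau_correlation(alpha, tau)
        assert r == pytest.approx(-1.0)

    def test_independent_variables_small_r(self, rng):
        """Permutation check: independent alpha and tau give r near 0."""
        alpha = rng.normal(0.5, 0.1, 200)
        tau = rng.normal(10.0, 2.0, 200)
        r, p = alpha_tau_correlation(alpha, tau)
        assert abs(r) < 0.2
        rs = [alpha_tau_correlation(rng.permutation(alpha), tau)[0] for _ in range(200)]
        assert np.quantile(np.abs(rs), 0.95) < 0.2

    def test_zero_variance_undefined(self):
        r, p = alpha_tau_correlation(np.full(5, 0.5), np.arange(5.0) + 1)
        assert np.isnan(r) and np.isnan(p)
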