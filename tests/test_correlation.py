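"""Correlator estimators, diffusion models and FCCS arithmetic."""

import numpy as np
import pytest

from ribbonflux import correlation as corr
from ribbonflux.correlation import (CorrelationCurve, DiffusionModelParams,
                                    IntensityTrace)


@pytest.fixture()
def noisy_trace():
    rng = np.random.default_rng(42)
    return IntensityTrace(rng.poisson(5.0, 4096).astype(float), dt=1e-3)


class TestAutocorrelate:
    def test_constant_trace_is_zero(self):
        tr = IntensityTrace(np.full(64, 3.0), dt=0.5)
        cur = corr.autocorrelate(tr, max_lag=5.0, scheme="direct")
        assert np.allclose(cur.g, 0.0)

    def test_alternating_sequence_exact(self):
        # mean 1, dF = +-1: perfectly anticorrelated at odd lags
        tr = IntensityTrace([2, 0, 2, 0, 2, 0, 2, 0], dt=1.0)
        cur = corr.autocorrelate(tr, max_lag=2.0, scheme="direct")
        assert cur.g[0] == pytest.approx(-1.0)
        assert cur.g[1] == pytest.approx(+1.0)

    def test_zero_mean_trace_rejected(self):
        tr = IntensityTrace([1.0, -1.0, 1.0, -1.0, 1.0, -1.0], dt=1.0)
        with pytest.raises(ValueError, match="normalis"):
            corr.autocorrelate(tr, max_lag=2.0)

    def test_max_lag_must_fit(self, noisy_trace):
        with pytest.raises(ValueError, match="max_lag"):
            corr.autocorrelate(noisy_trace, max_lag=3.0)

    def test_multiple_tau_matches_direct(self, noisy_trace):
        """The quasi-log scheme evaluates retained lags exactly, so it must
        agree with the brute-force linear estimator at shared lags."""
        direct = corr.autocorrelate(noisy_trace, 0.5, scheme="direct")
        mtau = corr.autocorrelate(noisy_trace, 0.5, scheme="multiple-tau")
        shared = np.isin(direct.lags, mtau.lags)
        ref = direct.g[shared]
        scale = np.maximum(np.abs(ref), 1e-30)
        assert np.all(np.abs(mtau.g - ref) / scale < 1e-8)

    def test_multiple_tau_lags_quasi_logarithmic(self, noisy_trace):
        cur = corr.autocorrelate(noisy_trace, 1.0, scheme="multiple-tau")
        spacing = np.diff(cur.lags / noisy_trace.dt)
        assert cur.lags.size < 150          # far fewer than 1000 linear lags
        assert spacing.max() > 32           # doubling levels reached

    def test_block_standard_errors(self, noisy_trace):
        cur = corr.autocorrelate(noisy_trace, 0.2, with_se=True)
        assert cur.se is not None and np.all(cur.se >= 0)


class TestCrosscorrelate:
    def test_self_cross_equals_auto(self, noisy_trace):
        auto = corr.autocorrelate(noisy_trace, 0.5)
        cross = corr.crosscorrelate(noisy_trace, noisy_trace, 0.5)
        assert np.allclose(auto.g, cross.g)

    def test_scale_invariance(self, noisy_trace):
        doubled = IntensityTrace(2 * noisy_trace.values, noisy_trace.dt)
        g1 = corr.crosscorrelate(noisy_trace, noisy_trace, 0.2).g
        g2 = corr.crosscorrelate(noisy_trace, doubled, 0.2).g
        assert np.allclose(g1, g2)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(7)
        a = IntensityTrace(rng.poisson(10.0, 20000).astype(float), 1e-3)
        b = IntensityTrace(rng.poisson(10.0, 20000).astype(float), 1e-3)
        cur = corr.crosscorrelate(a, b, 0.5, with_se=True)
        # individually ~95% of lags sit within 3 SE; none should be large
        within = np.abs(cur.g) < 3 * np.maximum(cur.se, 1e-6)
        assert within.mean() > 0.85    # block SEs carry only 4 df

        assert np.abs(cur.g).max() < 0.01

    def test_mismatched_traces_rejected(self, noisy_trace):
        other = IntensityTrace(noisy_trace.values[:-2], noisy_trace.dt)
        with pytest.raises(ValueError, match="length"):
            corr.crosscorrelate(noisy_trace, other, 0.2)


class TestModelG:
    def test_no_triplet_prefactor_is_identity(self):
        lags = np.logspace(-4, 1, 40)
        with_t = DiffusionModelParams(N=5, tau_d=0.1, T=0.0)
        plain = DiffusionModelParams(N=5, tau_d=0.1)
        assert np.allclose(corr.model_g(with_t, lags).g,
                           corr.model_g(plain, lags).g)

    def test_zero_lag_amplitude(self):
        p = DiffusionModelParams(N=5, gamma=1.0, baseline=1.0)
        assert corr.model_g(p, [0.0]).g[0] == pytest.approx(1.2)

    def test_half_amplitude_at_tau_d(self):
        # s_ratio -> inf: axial factor -> 1, lateral term 1/2 at tau = tau_d
        p = DiffusionModelParams(N=1, tau_d=2.0, s_ratio=1e9)
        assert corr.model_g(p, [2.0]).g[0] == pytest.approx(0.5, rel=1e-9)

    def test_strictly_decreasing_without_baseline(self):
        lags = np.logspace(-5, 2, 200)
        for s_ratio in (1.0, 3.0, 8.0):
            p = DiffusionModelParams(N=3, tau_d=0.5, s_ratio=s_ratio)
            g = corr.model_g(p, lags).g
            assert np.all(np.diff(g) < 0)

    def test_two_component_with_full_weight_equals_single(self):
        lags = np.logspace(-4, 1, 50)
        mix = DiffusionModelParams(N=4, tau_d=1.0,
                                   two_component=(1.0, 0.3, 5.0))
        single = DiffusionModelParams(N=4, tau_d=0.3)
        assert np.allclose(corr.model_g(mix, lags).g,
                           corr.model_g(single, lags).g)

    def test_as_printed_rendering(self):
        # literal printed form: axial power -1 and a trailing +1 baseline
        p = DiffusionModelParams(N=1, tau_d=1.0, s_ratio=2.0)
        cur = corr.model_g(p, [1.0], as_printed=True)
        assert cur.offset_convention == "plus-one"
        expected = 0.5 / (1 + 0.25) + 1.0
        assert cur.g[0] == pytest.approx(expected)

    def test_triplet_requires_tau(self):
        with pytest.raises(ValueError, match="tau_t"):
            DiffusionModelParams(N=1, tau_d=1.0, T=0.2)


class TestFitCorrelation:
    def test_noiseless_one_component_self_consistency(self):
        truth = DiffusionModelParams(N=10, tau_d=2.3)
        lags = np.logspace(-3, 2, 60)
        fit = corr.fit_correlation(
            corr.model_g(truth, lags),
            init=DiffusionModelParams(N=3, tau_d=0.5))
        assert fit.converged
        assert fit.N == pytest.approx(10, rel=1e-6)
        assert fit.tau_d == pytest.approx(2.3, rel=1e-6)

    def test_noiseless_two_component_self_consistency(self):
        # >95% slow pool plus a fast free minority
        truth = DiffusionModelParams(N=10, tau_d=1.0,
                                     two_component=(0.95, 2.3, 0.003))
        lags = np.logspace(-4, 2, 80)
        fit = corr.fit_correlation(
            corr.model_g(truth, lags), model_spec="two_component",
            init=DiffusionModelParams(N=5, tau_d=1.0,
                                      two_component=(0.7, 1.0, 0.01)))
        y, t1, t2 = fit.two_component      # normalised: tau_d1 < tau_d2
        assert fit.N == pytest.approx(10, rel=1e-4)
        assert 1 - y == pytest.approx(0.95, rel=1e-4)
        assert t1 == pytest.approx(0.003, rel=1e-4)
        assert t2 == pytest.approx(2.3, rel=1e-4)

    def test_triplet_fit_recovers_blinking(self):
        truth = DiffusionModelParams(N=5, tau_d=0.1, T=0.15, tau_t=5e-4)
        lags = np.logspace(-5, 1, 80)
        fit = corr.fit_correlation(
            corr.model_g(truth, lags),
            init=DiffusionModelParams(N=2, tau_d=0.05, T=0.05, tau_t=1e-3),
            fixed=("s_ratio", "a", "gamma", "baseline"))
        assert fit.T == pytest.approx(0.15, rel=1e-4)
        assert fit.tau_t == pytest.approx(5e-4, rel=1e-4)

    def test_too_few_points_rejected(self):
        p = DiffusionModelParams(N=1, tau_d=1.0)
        curve = corr.model_g(p, [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="lag points"):
            corr.fit_correlation(curve)


class TestDiffusionCoefficient:
    def test_direct_arithmetic(self):
        assert corr.diffusion_coefficient(1.0, 0.2) == pytest.approx(0.01)

    def test_factor_two_variant(self):
        assert corr.diffusion_coefficient(1.0, 0.2, geometry_factor=2) \
            == pytest.approx(0.02)

    def test_beam_radius_inversion(self):
        # vesicle anchor point: D = 0.005 um^2/s at residence time 4.61 s
        assert corr.beam_radius_from_d(0.005, 4.61) \
            == pytest.approx(0.3036, abs=5e-4)

    def test_clathrin_d_from_calibrated_beam(self):
        r0 = corr.beam_radius_from_d(0.005, 4.61)
        d = corr.diffusion_coefficient(2.3, r0)
        assert d == pytest.approx(0.0096, rel=0.05)

    @pytest.mark.parametrize("tau_d,r0", [(0.0, 0.2), (1.0, -1.0)])
    def test_invalid_inputs(self, tau_d, r0):
        with pytest.raises(ValueError):
            corr.diffusion_coefficient(tau_d, r0)


class TestNBound:
    def test_no_crosstalk_reduces_to_product_rule(self):
        res = corr.n_bound(10, 10, 20, q=0.0)
        assert res.n_bound == pytest.approx(5.0)
        assert res.frac_green_bound == pytest.approx(0.5)
        assert res.frac_red_bound == pytest.approx(0.5)

    def test_crosstalk_correction(self):
        # 10*(10 + 0.1*10)/20 - 0.1*10 = 4.5
        assert corr.n_bound(10, 10, 20, q=0.1).n_bound == pytest.approx(4.5)

    def test_no_cross_correlation_means_nothing_bound(self):
        assert corr.n_bound(10, 10, 1e12, q=0.0).n_bound \
            == pytest.approx(0.0, abs=1e-9)

    def test_overcorrection_clips_to_zero(self):
        res = corr.n_bound(10, 10, 1e6, q=0.5)
        assert res.n_bound == 0.0 and res.clipped

    def test_fractions_bounded(self):
        res = corr.n_bound(2.0, 3.0, 1.0, q=0.0)
        assert 0 <= res.frac_green_bound <= 1
        assert 0 <= res.frac_red_bound <= 1


class TestContainers:
    def test_lags_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            CorrelationCurve(lags=[0.2, 0.1], g=[1.0, 1.0])

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            IntensityTrace([1.0], dt=0.1)
        with pytest.raises(ValueError):
            IntensityTrace([1.0, np.nan], dt=0.1)
        with pytest.raises(ValueError):
            IntensityTrace([1.0, 2.0], dt=-1.0)
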