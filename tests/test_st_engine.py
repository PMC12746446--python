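"""Serial tempering: scanning, Simpson bias construction, heat-bath jumps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from samti import (BiasProfile, HarmonicOscillator, LambdaGrid,
                   build_bias_simpson, heat_bath_jump,
                   heat_bath_probabilities, jump_log_weights,
                   sequential_scan)
from samti.st_engine import ConfigurationError
from samti.var_adapt import VarianceTracker

from conftest import make_sampler, make_walker


class TestLambdaGrid:
    def test_default_grid_spans_unit_interval(self, grid101):
        v = grid101.values
        assert v[0] == 0.0 and v[-1] == 1.0
        assert grid101.delta_lambda == pytest.approx(0.01)
        assert np.allclose(np.diff(v), 0.01)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            LambdaGrid(1)


class TestSequentialScan:
    def test_lambda_independent_model_gives_zero_means(self):
        m = HarmonicOscillator(2.0, 2.0)
        grid = LambdaGrid(11)
        means, counts, _ = sequential_scan(m, grid, make_sampler(),
                                           make_walker(m, seed=1), 50)
        assert np.allclose(means, 0.0)
        assert counts.sum() == 11 * 50

    def test_harmonic_means_match_conditional_moments(self, harmonic):
        grid = LambdaGrid(11)
        tracker = VarianceTracker(11)
        means, counts, _ = sequential_scan(
            harmonic, grid, make_sampler(step_size=1.0),
            make_walker(harmonic, seed=2), 4000, tracker=tracker)
        for i, lam in enumerate(grid.values):
            expect = harmonic.analytic_dudl_mean(lam)
            se = math.sqrt(harmonic.analytic_dudl_var(lam) / counts[i]) * 3
            # 3x allowance on top of the iid SE for autocorrelation
            assert abs(means[i] - expect) < 3 * se
        assert np.array_equal(tracker.counts, counts)

    def test_record_interval_bookkeeping(self, harmonic):
        grid = LambdaGrid(5)
        s = make_sampler(record_interval=10)
        means, counts, _ = sequential_scan(harmonic, grid, s,
                                           make_walker(harmonic), 100)
        assert counts.sum() == 5 * (100 // 10)


class TestSimpsonBias:
    def test_zero_means_give_zero_bias(self, grid101):
        bias = build_bias_simpson(np.zeros(101), grid101)
        assert np.array_equal(bias.f_values, np.zeros(101))

    def test_constant_means_integrate_exactly_at_even_windows(self, grid101):
        c = 2.5
        bias = build_bias_simpson(np.full(101, c), grid101)
        lam = grid101.values
        assert np.allclose(bias.f_values[::2], -c * lam[::2], atol=1e-14)

    def test_linear_means_integrate_exactly_at_even_windows(self, grid101):
        lam = grid101.values
        bias = build_bias_simpson(lam.copy(), grid101)
        assert np.allclose(bias.f_values[::2], -0.5 * lam[::2] ** 2,
                           atol=1e-14)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(coeffs=hst.lists(hst.floats(-5, 5), min_size=4, max_size=4))
    def test_cubic_exactness_property(self, coeffs):
        """Simpson integrates polynomials up to degree 3 exactly (even i)."""
        grid = LambdaGrid(21)
        lam = grid.values
        y = np.polyval(coeffs, lam)
        p_int = np.polyint(np.asarray(coeffs))
        exact = np.polyval(p_int, lam) - np.polyval(p_int, 0.0)
        bias = build_bias_simpson(y, grid)
        assert np.allclose(bias.f_values[::2], -exact[::2], atol=1e-9)

    def test_harmonic_analytic_means_reproduce_free_energy(self, harmonic,
                                                           grid101):
        """Bias equals -(1/2) ln(k(lambda)/k0) within 1e-6 at even windows."""
        means = np.array([harmonic.analytic_dudl_mean(l)
                          for l in grid101.values])
        bias = build_bias_simpson(means, grid101)
        k = np.array([harmonic.spring(l) for l in grid101.values])
        exact = -0.5 * np.log(k / harmonic.k0)
        assert np.abs(bias.f_values[::2] - exact[::2]).max() < 1e-6

    def test_gauge_and_errors(self, grid101):
        bias = build_bias_simpson(np.random.default_rng(0).normal(size=101),
                                  grid101)
        assert bias.f_values[0] == 0.0
        with pytest.raises(ConfigurationError):
            build_bias_simpson(np.zeros(5), grid101)  # length mismatch
        with pytest.raises(ConfigurationError):
            build_bias_simpson(np.zeros(2), LambdaGrid(2))


class TestJumpWeights:
    def test_lambda_independent_model_zero_bias_gives_zero_weights(self):
        m = HarmonicOscillator(2.0, 2.0)
        grid = LambdaGrid(11)
        st = make_walker(m, lam_index=4)
        st.coords = np.array([1.3])
        logw = jump_log_weights(st, m, grid, BiasProfile.zeros(11))
        assert np.allclose(logw, 0.0)

    def test_energy_bias_cancellation(self, harmonic):
        """dU = +1 kT compensated by dF = -1 kT gives log-weight zero."""
        grid = LambdaGrid(2)
        st = make_walker(harmonic, lam_index=0)
        x = math.sqrt(2.0 / 3.0)  # U(1) - U(0) = 1.5 x^2 = 1 kT
        st.coords = np.array([x])
        bias = BiasProfile(np.array([0.0, -1.0]))
        logw = jump_log_weights(st, harmonic, grid, bias)
        assert logw[0] == 0.0
        assert logw[1] == pytest.approx(0.0, abs=1e-12)

    def test_current_entry_is_zero(self, harmonic, grid101):
        st = make_walker(harmonic, lam_index=37)
        st.coords = np.array([0.8])
        bias = BiasProfile(np.linspace(0, -1, 101))
        logw = jump_log_weights(st, harmonic, grid101, bias)
        assert logw[37] == 0.0


class TestHeatBathJump:
    def test_probabilities_exclude_current_and_normalize(self):
        p = heat_bath_probabilities(np.zeros(5), 2)
        assert p[2] == 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p[[0, 1, 3, 4]], 0.25)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(logw=hst.lists(hst.floats(-30, 30), min_size=2, max_size=12),
           idx=hst.integers(0, 11))
    def test_normalization_property(self, logw, idx):
        logw = np.asarray(logw)
        idx = idx % logw.size
        p = heat_bath_probabilities(logw, idx)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[idx] == 0.0

    def test_log_three_ratio(self):
        """Two candidates separated by ln 3 -> probabilities 0.75 / 0.25."""
        logw = np.array([math.log(3.0), 0.0, 0.0])
        p = heat_bath_probabilities(logw, 2)
        assert p[0] == pytest.approx(0.75, abs=1e-12)
        assert p[1] == pytest.approx(0.25, abs=1e-12)

    def test_two_windows_always_jump(self, rng):
        for _ in range(10):
            assert heat_bath_jump(np.array([0.0, -5.0]), 0, rng) == 1

    def test_symmetric_candidates_empirical_frequency(self, rng):
        counts = np.zeros(3, dtype=int)
        logw = np.zeros(3)
        for _ in range(100_000):
            counts[heat_bath_jump(logw, 0, rng)] += 1
        sigma = math.sqrt(0.25 * 100_000)
        assert counts[0] == 0
        assert abs(counts[1] - 50_000) < 3 * sigma

    def test_all_candidates_vanishing_declines_jump(self, rng):
        logw = np.array([-np.inf, 0.0, -np.inf])
        assert heat_bath_jump(logw, 1, rng) == 1

    def test_overflow_safety(self, rng):
        logw = np.array([1e4, 1e4 - math.log(3.0), -np.inf])
        p = heat_bath_probabilities(logw, 2)
        assert p[0] == pytest.approx(0.75, abs=1e-12)


class TestFlatHistogram:
    def test_exact_bias_flattens_visitation_small(self, harmonic):
        """With the exact bias installed, visitation is uniform (chi-square).

        Reduced-size version of the flat-histogram design property; the
        full-scale run lives in the acceptance suite.
        """
        from scipy import stats
        grid = LambdaGrid(21)
        k = np.array([harmonic.spring(l) for l in grid.values])
        bias = BiasProfile(-0.5 * np.log(k))
        s = make_sampler(step_size=1.0)
        st = make_walker(harmonic, seed=9, lam_index=10)
        visits = np.zeros(21, dtype=int)
        for _ in range(20_000):
            s.propagate(st, harmonic, 10, grid.values[st.lam_index])
            st.lam_index = heat_bath_jump(
                jump_log_weights(st, harmonic, grid, bias),
                st.lam_index, st.rng)
            visits[st.lam_index] += 1
        _, p = stats.chisquare(visits)
        assert p > 0.01
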