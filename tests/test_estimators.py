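"""TI quadrature and the autocorrelation / sampling-quality stack."""

import math

import numpy as np
import pytest

from samti import (HarmonicOscillator, LambdaGrid, autocorrelation,
                   effective_samples, replicate_spread, sampling_quality,
                   standard_error, statistical_inefficiency, ti_integrate,
                   ti_standard_error)
from samti.estimators import (ZeroVarianceError, apply_burn_in,
                              quadrature_weights)
from samti.fixtures import ar1_series


def brute_force_g(series):
    """Independent literal implementation: full rho_k table, explicit sum.

    rho_k = (1/N) sum_t (x_t - mu)(x_{t+k} - mu) / var, summed from k = 1
    until the first nonpositive value.
    """
    x = [float(v) for v in series]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    total = 0.0
    for k in range(1, n):
        cov = sum((x[t] - mu) * (x[t + k] - mu) for t in range(n - k)) / n
        rho = cov / var
        if rho <= 0.0:
            break
        total += rho
    return max(1.0, 1.0 + 2.0 * total)


class TestTiIntegrate:
    def test_zero_means_zero_dg(self, grid101):
        assert ti_integrate(np.zeros(101), grid101).dg == 0.0

    def test_constant_means_exact(self, grid101):
        assert ti_integrate(np.full(101, 2.7), grid101).dg == \
            pytest.approx(2.7, abs=1e-12)

    def test_harmonic_analytic_means_recover_ln2(self, harmonic, grid101):
        means = np.array([harmonic.analytic_dudl_mean(l)
                          for l in grid101.values])
        res = ti_integrate(means, grid101, "simpson")
        # composite-Simpson error bound h^4 (b-a) max|f''''| / 180 ~ 2e-8
        assert abs(res.dg - math.log(2.0)) < 5e-8

    def test_trapezoid_rule_available(self, harmonic, grid101):
        means = np.array([harmonic.analytic_dudl_mean(l)
                          for l in grid101.values])
        res = ti_integrate(means, grid101, "trapezoid")
        assert abs(res.dg - math.log(2.0)) < 1e-4

    def test_even_window_count_falls_back_on_last_panel(self, harmonic):
        grid = LambdaGrid(10)
        means = np.array([harmonic.analytic_dudl_mean(l) for l in grid.values])
        res = ti_integrate(means, grid, "simpson")
        assert abs(res.dg - math.log(2.0)) < 1e-3

    def test_unsampled_window_rejected(self, grid101):
        with pytest.raises(ValueError):
            ti_integrate(np.zeros(101), grid101,
                         per_window_counts=np.r_[0, np.ones(100)])


class TestQuadratureWeights:
    @pytest.mark.parametrize("n", [3, 21, 101, 10])
    def test_weights_reproduce_quadrature(self, n, harmonic):
        grid = LambdaGrid(n)
        means = np.array([harmonic.analytic_dudl_mean(l) for l in grid.values])
        w = quadrature_weights(n, grid.delta_lambda, "simpson")
        assert float(w @ means) == \
            pytest.approx(ti_integrate(means, grid, "simpson").dg, abs=1e-12)

    def test_trapezoid_weights_sum_to_one(self):
        w = quadrature_weights(11, 0.1, "trapezoid")
        assert w.sum() == pytest.approx(1.0)


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        assert autocorrelation(rng.normal(size=100), 0) == 1.0

    def test_alternating_sequence(self):
        x = np.resize([1.0, -1.0], 1000)
        rho = autocorrelation(x, 1)
        assert rho == pytest.approx(-1.0, abs=2.0 / 1000)

    def test_white_noise_near_zero(self, rng):
        n = 100_000
        assert abs(autocorrelation(rng.normal(size=n), 1)) < 3.0 / math.sqrt(n)

    def test_errors(self, rng):
        with pytest.raises(ZeroVarianceError):
            autocorrelation(np.ones(50), 1)
        with pytest.raises(ValueError):
            autocorrelation(rng.normal(size=10), 20)


class TestStatisticalInefficiency:
    def test_matches_brute_force_exactly(self, rng):
        """Oracle equivalence on short series of several correlation types."""
        series = [
            rng.normal(size=200),
            ar1_series(0.8, 500, np.random.default_rng(2)),
            ar1_series(0.3, 2000, np.random.default_rng(3)),
            np.repeat(rng.normal(size=150), 2),
        ]
        for x in series:
            assert statistical_inefficiency(x) == \
                pytest.approx(brute_force_g(x), rel=1e-12)

    def test_white_noise_unit_inefficiency(self, rng):
        g = statistical_inefficiency(rng.normal(size=100_000))
        assert g == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("phi", [0.5, 0.9])
    def test_ar1_closed_form(self, phi):
        """g = (1 + phi)/(1 - phi) within 15% at N = 1e5."""
        x = ar1_series(phi, 100_000, np.random.default_rng(42))
        expect = (1 + phi) / (1 - phi)
        assert statistical_inefficiency(x) == pytest.approx(expect, rel=0.15)

    def test_constant_series_error(self):
        with pytest.raises(ZeroVarianceError):
            statistical_inefficiency(np.full(100, 2.0))


class TestEffectiveSamples:
    def test_white_noise(self, rng):
        n_eff, eta = effective_samples(rng.normal(size=1000))
        assert n_eff == pytest.approx(1000, rel=0.15)
        assert eta == pytest.approx(1.0, rel=0.15)

    def test_definition_consistency(self, rng):
        x = ar1_series(0.7, 5000, rng)
        g = statistical_inefficiency(x)
        n_eff, eta = effective_samples(x)
        assert n_eff == pytest.approx(x.size / g)
        assert eta == pytest.approx(1.0 / g)

    def test_duplicated_series_halves_efficiency(self, rng):
        x = rng.normal(size=4000)
        _, eta1 = effective_samples(x)
        _, eta2 = effective_samples(np.repeat(x, 2))
        assert eta2 == pytest.approx(eta1 / 2, rel=0.2)


class TestStandardError:
    def test_iid_scale(self, rng):
        x = rng.normal(size=100)
        se = standard_error(x)
        assert se == pytest.approx(0.1, rel=0.5)

    def test_homogeneity(self, rng):
        x = ar1_series(0.5, 2000, rng)
        assert standard_error(3.0 * x) == pytest.approx(3 * standard_error(x))

    def test_correlated_series_inflates_se(self):
        """AR(1) phi=0.9 vs white noise at equal N, sigma: ratio ~ sqrt(19)."""
        n = 100_000
        x = ar1_series(0.9, n, np.random.default_rng(7))
        w = np.random.default_rng(8).normal(size=n)
        x = (x - x.mean()) / x.std()
        w = (w - w.mean()) / w.std()
        ratio = standard_error(x) / standard_error(w)
        assert ratio == pytest.approx(math.sqrt(19.0), rel=0.15)


class TestReplicateSpread:
    def test_identical_means_zero(self):
        assert replicate_spread([1.5, 1.5, 1.5]) == 0.0

    def test_two_point_hand_value(self):
        assert replicate_spread([0.0, 2.0]) == pytest.approx(math.sqrt(2.0))

    def test_translation_invariance(self, rng):
        a = rng.normal(size=8)
        assert replicate_spread(a + 10.0) == pytest.approx(replicate_spread(a))

    def test_needs_two(self):
        with pytest.raises(ValueError):
            replicate_spread([1.0])


class TestSamplingQuality:
    @pytest.mark.parametrize("ratio,flag", [(1.0, "ok"), (2.0, "ok"),
                                            (3.0, "warning"), (5.0, "warning"),
                                            (6.0, "severe")])
    def test_flag_thresholds(self, ratio, flag):
        r, f = sampling_quality(ratio, 1.0)
        assert r == ratio and f == flag

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            sampling_quality(1.0, 0.0)

    def test_trapped_replicates_flagged(self):
        """Half the replicates stuck in one well must trip the diagnostic."""
        from samti.fixtures import generate_fixture
        frame = generate_fixture("dual_well_replicates",
                                 {"n": 1000, "separation": 8.0}, seed=0)
        means, ses = [], []
        for _, sub in frame.groupby("replica"):
            x = sub["dudl"].to_numpy()
            means.append(x.mean())
            ses.append(standard_error(x))
        ratio, flag = sampling_quality(replicate_spread(means),
                                       float(np.mean(ses)))
        assert ratio > 2.0


class TestTiStandardError:
    def test_iid_windows_analytic(self):
        """Propagated SE matches the closed form for equal iid windows."""
        grid = LambdaGrid(11)
        s2 = np.full(11, 4.0)
        neff = np.full(11, 100.0)
        w = quadrature_weights(11, grid.delta_lambda, "simpson")
        expect = math.sqrt(float(np.sum(w ** 2 * 4.0 / 100.0)))
        assert ti_standard_error(s2, neff, grid) == pytest.approx(expect)

    def test_nonpositive_neff_rejected(self):
        grid = LambdaGrid(3)
        with pytest.raises(ValueError):
            ti_standard_error(np.ones(3), np.array([1.0, 0.0, 1.0]), grid)


def test_burn_in_discards_leading_fraction():
    x = np.arange(100)
    assert apply_burn_in(x, 0.1)[0] == 10
    assert apply_burn_in(x, 0.0).size == 100
    with pytest.raises(ValueError):
        apply_burn_in(x, 1.0)
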