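import itertools

import numpy as np
import pytest
from scipy import stats

from pi0bench import (METHODS, bum_mixture_pvalues, estimate_all,
                      estimate_pi0_ch04, estimate_pi0_pc04, estimate_pi0_pm03,
                      estimate_pi0_st03, estimate_pi0_zg04,
                      uniform_grid_pvalues)
from pi0bench.estimators import bum_loglik, smoothing_spline_fit


class TestZG04:
    def test_uniform_grid_slopes_near_one(self):
        # on the exact grid p_(i) = i/M every chord to (1,1) has slope 1
        M = 10_000
        p = np.arange(1, M + 1) / M
        est = estimate_pi0_zg04(p)
        assert est.pi0_hat == pytest.approx(1.0, abs=1e-6)

    def test_four_value_example(self):
        # selected slopes {(1-2/4)/(1-0.5), (1-3/4)/(1-0.6)} = {1.0, 0.625}
        est = estimate_pi0_zg04(np.array([0.1, 0.5, 0.6, 0.8]))
        assert est.pi0_hat == pytest.approx(0.8125)
        assert est.diagnostics["n_slopes"] == 2

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="widen"):
            estimate_pi0_zg04(np.array([0.1, 0.2, 0.3]), t1=0.5, t2=1.0)

    def test_matches_brute_force_enumeration(self, mixed_pvalues):
        # independent oracle: enumerate the slope set directly
        p = np.sort(mixed_pvalues.p)
        M = p.size
        slopes = [(1 - (i + 1) / M) / (1 - p[i]) for i in range(M)
                  if 0.5 <= p[i] <= 1.0 and p[i] < 1.0 and (i + 1) < M]
        expected = min(1.0, max(0.0, float(np.median(slopes))))
        assert estimate_pi0_zg04(mixed_pvalues).pi0_hat == pytest.approx(expected)


class TestST03:
    def test_lambda_zero_estimate_is_one(self):
        est = estimate_pi0_st03(np.array([0.01, 0.02, 0.6, 0.8]),
                                lambda_grid=np.array([0.0, 0.05, 0.1, 0.2]))
        assert est.diagnostics["pi0_lambda"][0] == pytest.approx(1.0)
        # #{p > 0.05} = 2 of 4 -> 2 / (4 * 0.95)
        assert est.diagnostics["pi0_lambda"][1] == pytest.approx(2 / 3.8)

    def test_uniform_midgrid_tail_fraction(self):
        p = (np.arange(1, 11) - 0.5) / 10
        est = estimate_pi0_st03(p, lambda_grid=np.array([0.0, 0.2, 0.5, 0.8]))
        # #{p > 0.5} = 5 -> 5 / (10 * 0.5) = 1
        assert est.diagnostics["pi0_lambda"][2] == pytest.approx(1.0)

    def test_too_few_grid_points_error(self):
        with pytest.raises(ValueError):
            estimate_pi0_st03(np.array([0.1, 0.9]),
                              lambda_grid=np.array([0.0, 0.5, 0.9]))

    def test_spline_reproduces_linear_data_exactly(self):
        # zero roughness: the smoothing spline passes through linear data
        x = np.linspace(0, 1, 30)
        y = 0.3 + 0.5 * x
        np.testing.assert_allclose(smoothing_spline_fit(x, y, df=3.0), y,
                                   atol=1e-8)

    def test_spline_matches_independent_reference_fit(self, bum_sample):
        # frozen oracle: R's smooth.spline(lambda, pi0_lambda, df=3)
        # evaluated at lambda = 0.95 on this exact sample gives 0.7432641
        est = estimate_pi0_st03(bum_sample)
        assert est.pi0_hat == pytest.approx(0.74326, abs=5e-3)


class TestPM03:
    def test_uniform_only_mixture_returns_one(self, uniform_grid_1000):
        est = estimate_pi0_pm03(uniform_grid_1000)
        assert est.pi0_hat == pytest.approx(1.0, abs=1e-3)

    def test_parameter_recovery_on_bum_draws(self):
        pi0s, a_hats, w_hats = [], [], []
        for seed in range(5):
            pv = bum_mixture_pvalues(5000, w=0.7, a=0.2, seed=seed)
            est = estimate_pi0_pm03(pv)
            pi0s.append(est.pi0_hat)
            a_hats.append(est.diagnostics["a_hat"])
            w_hats.append(est.diagnostics["w_hat"])
        assert np.mean(a_hats) == pytest.approx(0.2, abs=0.05)
        assert np.mean(w_hats) == pytest.approx(0.7, abs=0.05)
        # w + (1-w)*a = 0.76 upper-bounds pi0 = 0.7
        assert np.mean(pi0s) >= 0.7

    def test_mle_beats_grid_search(self, bum_sample):
        est = estimate_pi0_pm03(bum_sample)
        p = np.clip(bum_sample.p, 1e-10, 1.0)
        grid = [bum_loglik(a, w, p)
                for a in np.linspace(1e-4, 1.0, 50)
                for w in np.linspace(0.0, 1.0, 50)]
        assert est.diagnostics["loglik"] >= max(grid) - 1e-6


class TestPC04:
    def test_uniform_grid_density_is_one(self, uniform_grid_1000):
        assert estimate_pi0_pc04(uniform_grid_1000).pi0_hat == pytest.approx(
            1.0, abs=1e-6)

    def test_mixture_minimum_between_uniform_share_and_one(self):
        pv = bum_mixture_pvalues(5000, w=0.5, a=0.1, seed=3)
        est = estimate_pi0_pc04(pv)
        # true density minimum is 0.5 + 0.5*0.1*1^(-0.9) ~ 0.55 at p = 1
        assert 0.45 <= est.pi0_hat < 1.0

    def test_too_few_pvalues_error(self):
        with pytest.raises(ValueError):
            estimate_pi0_pc04(np.array([0.2, 0.8]))

    def test_ties_are_merged(self):
        p = np.concatenate([np.full(50, 0.25), np.linspace(0.01, 0.99, 450)])
        est = estimate_pi0_pc04(p)  # must not blow up on zero spacings
        assert 0.0 <= est.pi0_hat <= 1.0


class TestCh04:
    def test_uniform_grid_recovers_identity_cdf(self, uniform_grid_1000):
        assert estimate_pi0_ch04(uniform_grid_1000).pi0_hat == pytest.approx(
            1.0, abs=0.02)

    def test_fitted_density_nonnegative(self, mixed_pvalues):
        from scipy.interpolate import BSpline
        est = estimate_pi0_ch04(mixed_pvalues)
        spl = BSpline(est.diagnostics["knots"], est.diagnostics["coef"], 3)
        dens = spl.derivative()(np.linspace(0, 1, 2001))
        assert dens.min() >= -1e-8

    def test_mixture_density_minimum_recovered(self):
        pv = bum_mixture_pvalues(10_000, w=0.8, a=0.2, seed=5)
        est = estimate_pi0_ch04(pv)
        # analytic minimum of the generating density: 0.8 + 0.2*0.2 = 0.84
        assert est.pi0_hat == pytest.approx(0.84, abs=0.1)

    def test_insufficient_data_error(self):
        with pytest.raises(ValueError):
            estimate_pi0_ch04(np.linspace(0.1, 0.9, 10), n_knots=10)


class TestCommonProperties:
    def test_all_estimates_in_unit_interval(self, mixed_pvalues):
        for est in estimate_all(mixed_pvalues).values():
            assert 0.0 <= est.pi0_hat <= 1.0

    def test_permutation_invariance(self, mixed_pvalues):
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(mixed_pvalues.p)
        a = estimate_all(mixed_pvalues.p)
        b = estimate_all(shuffled)
        for m in METHODS:
            # identical up to float summation order in the likelihoods
            assert a[m].pi0_hat == pytest.approx(b[m].pi0_hat, abs=1e-6)

    def test_uniform_grid_estimates_near_one(self, uniform_grid_1000):
        ests = estimate_all(uniform_grid_1000)
        for m in ("ZG04", "ST03", "PC04"):
            assert ests[m].pi0_hat >= 0.95, m
        assert ests["Ch04"].pi0_hat >= 0.9

    def test_unknown_method_rejected(self, uniform_grid_1000):
        with pytest.raises(ValueError):
            estimate_all(uniform_grid_1000, methods=("BH95",))
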