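"""Depth mixture models: densities, EM, K-S fitness, bootstrap."""

import mpmath
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radml.depth_model import (DepthModelError, DepthModelSpec,
                               DepthObservations, EMConfig,
                               balanced_bootstrap_indices, bootstrap_em,
                               composite_fraction, composite_posterior, fit_em,
                               fit_single, ks_fitness, mixture_density,
                               repeat_depth_threshold)

mpmath.mp.dps = 40


def mp_poisson(k, lam):
    lam = mpmath.mpf(lam)
    return lam ** k * mpmath.e ** (-lam) / mpmath.factorial(k)


def mp_mixture(k, C, weights):
    return sum(mpmath.mpf(a) * mp_poisson(k, (i + 1) * C)
               for i, a in enumerate(weights))


class TestMixtureDensity:
    def test_single_poisson_analytic(self):
        model = DepthModelSpec("poisson", 1.0, np.array([1.0]))
        assert mixture_density(0, model) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_degenerate_mixture_equals_single(self):
        mixed = DepthModelSpec("mixed_poisson", 17.0, np.array([1.0, 0.0, 0.0]))
        single = DepthModelSpec("poisson", 17.0, np.array([1.0]))
        ks = np.arange(201)
        np.testing.assert_allclose(mixture_density(ks, mixed),
                                   mixture_density(ks, single), rtol=1e-12)

    @pytest.mark.parametrize("k", [25, 60, 95])
    def test_matches_arbitrary_precision_oracle(self, k):
        C, weights = 30.0, [0.8, 0.15, 0.05]
        model = DepthModelSpec("mixed_poisson", C, np.array(weights))
        expected = float(mp_mixture(k, C, weights))
        assert mixture_density(k, model) == pytest.approx(expected, rel=1e-12)

    def test_negative_depth_rejected(self):
        model = DepthModelSpec("poisson", 5.0, np.array([1.0]))
        with pytest.raises(DepthModelError):
            mixture_density(-1, model)

    def test_poisson_mixture_sums_to_one(self):
        model = DepthModelSpec("mixed_poisson", 30.0, np.array([0.7, 0.2, 0.1]))
        ks = np.arange(10 * 3 * 30)
        assert mixture_density(ks, model).sum() == pytest.approx(1.0, abs=1e-9)


class TestFitSingle:
    def test_poisson_mean(self):
        fit = fit_single(DepthObservations([3, 5, 7]), "poisson")
        assert fit.model.C == pytest.approx(5.0)
        assert fit.model.M == 1 and fit.converged

    def test_constant_depths_normal_degenerate(self):
        with pytest.raises(DepthModelError, match="degenerate"):
            fit_single(DepthObservations([8] * 50), "normal")

    def test_poisson_recovery_sampling(self, rng):
        d = rng.poisson(40, size=10_000)
        fit = fit_single(DepthObservations(np.maximum(d, 1)), "poisson")
        assert abs(fit.model.C - 40) < 3 * np.sqrt(40 / 10_000) + 0.01


class TestFitEM:
    def test_single_component_degenerates_to_mean(self, rng):
        d = np.maximum(rng.poisson(25, size=500), 1)
        fit = fit_em(DepthObservations(d), "mixed_poisson", EMConfig(M=1))
        assert fit.model.C == pytest.approx(d.mean(), abs=1e-6)
        assert fit.model.weights[0] == pytest.approx(1.0)

    def test_parameter_recovery_mixed_poisson(self, rng):
        comp = rng.choice(3, size=50_000, p=[0.85, 0.10, 0.05])
        d = rng.poisson(30.0 * (comp + 1))
        fit = fit_em(DepthObservations(d), "mixed_poisson", EMConfig())
        assert abs(fit.model.C - 30) <= 0.5
        assert np.abs(fit.model.weights - [0.85, 0.10, 0.05]).max() <= 0.01

    def test_log_likelihood_never_decreases(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            comp = r.choice(3, size=3000, p=[0.7, 0.2, 0.1])
            d = r.poisson(20.0 * (comp + 1))
            fit = fit_em(DepthObservations(np.maximum(d, 1)), "mixed_poisson",
                         EMConfig())
            lls = np.array(fit.log_likelihoods)
            assert (np.diff(lls) >= -1e-10 * np.abs(lls[:-1])).all()

    def test_component1_update_matches_em_fit(self, rng):
        """The as-published component-1 C update lands on the same estimate."""
        comp = rng.choice(3, size=30_000, p=[0.85, 0.10, 0.05])
        d = rng.poisson(30.0 * (comp + 1))
        obs = DepthObservations(d)
        fit_all = fit_em(obs, "mixed_poisson", EMConfig(c_update="all"))
        fit_c1 = fit_em(obs, "mixed_poisson", EMConfig(c_update="component1"))
        assert fit_c1.model.C == pytest.approx(fit_all.model.C, abs=0.1)
        np.testing.assert_allclose(fit_c1.model.weights, fit_all.model.weights,
                                   atol=0.005)

    def test_mixed_normal_two_separated_components(self, rng):
        comp = rng.choice(2, size=8000, p=[0.7, 0.3])
        d = np.maximum(np.round(rng.normal(100 * (comp + 1), 20)), 1).astype(int)
        fit = fit_em(DepthObservations(d), "mixed_normal", EMConfig(M=2))
        assert np.abs(fit.model.weights - [0.7, 0.3]).max() < 0.03
        assert fit.model.C == pytest.approx(100, abs=3)

    def test_weights_stay_on_simplex(self, rng):
        d = np.maximum(rng.poisson(12, size=400), 1)
        fit = fit_em(DepthObservations(d), "mixed_poisson", EMConfig(M=3))
        w = fit.model.weights
        assert (w >= 0).all() and w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_small_sample_warns(self, rng):
        d = np.maximum(rng.poisson(10, size=12), 1)
        with pytest.warns(UserWarning, match="unstable"):
            fit_em(DepthObservations(d), "mixed_poisson", EMConfig(M=3))

    def test_parameter_recovery_over_seeds(self):
        """Median relative error of C < 2% and of a_1 < 0.02 at n=30,000."""
        c_errs, a_errs = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            true_a = [0.8, 0.12, 0.08]
            comp = r.choice(3, size=30_000, p=true_a)
            d = r.poisson(25.0 * (comp + 1))
            fit = fit_em(DepthObservations(d), "mixed_poisson", EMConfig())
            c_errs.append(abs(fit.model.C - 25) / 25)
            a_errs.append(abs(fit.model.weights[0] - true_a[0]))
        assert np.median(c_errs) < 0.02
        assert np.median(a_errs) < 0.02


class TestCompositeQuantities:
    model = DepthModelSpec("mixed_poisson", 30.0, np.array([0.9, 0.07, 0.03]))

    def test_composite_fraction(self):
        assert composite_fraction(
            DepthModelSpec("mixed_poisson", 10.0, np.array([1.0, 0.0, 0.0]))) == 0.0
        m = DepthModelSpec("mixed_poisson", 125.0, np.array([0.83, 0.09, 0.08]))
        assert composite_fraction(m) == pytest.approx(0.17)

    def test_posterior_zero_for_single_component(self):
        single = DepthModelSpec("poisson", 30.0, np.array([1.0]))
        assert composite_posterior(100, single) == 0.0

    def test_posterior_matches_oracle_at_3C(self):
        k, C, weights = 90, 30.0, [0.9, 0.07, 0.03]
        num = sum(mpmath.mpf(a) * mp_poisson(k, (i + 1) * C)
                  for i, a in enumerate(weights) if i >= 1)
        expected = float(num / mp_mixture(k, C, weights))
        assert composite_posterior(k, self.model) == pytest.approx(expected, rel=1e-10)

    def test_posterior_approaches_one_in_tail(self):
        assert composite_posterior(500, self.model) > 1 - 1e-9

    def test_threshold_matches_grid_scan(self):
        post = composite_posterior(np.arange(501), self.model)
        expected = int(np.flatnonzero(post > 0.5)[0])
        assert repeat_depth_threshold(self.model) == expected

    def test_threshold_monotone_in_a1(self):
        tight = DepthModelSpec("mixed_poisson", 30.0, np.array([0.999, 5e-4, 5e-4]))
        assert repeat_depth_threshold(tight) > repeat_depth_threshold(self.model)

    def test_threshold_mixed_normal_tiny_sigma_between_C_and_2C(self):
        m = DepthModelSpec("mixed_normal", 30.0, np.array([0.9, 0.07, 0.03]),
                           sigmas=np.array([1.0, 1.0, 1.0]))
        t = repeat_depth_threshold(m)
        assert 30 < t < 60

    def test_threshold_undefined_for_single_component(self):
        with pytest.raises(DepthModelError):
            repeat_depth_threshold(DepthModelSpec("poisson", 30.0, np.array([1.0])))


class TestKSFitness:
    def test_statistic_in_unit_interval(self, rng):
        d = np.maximum(rng.poisson(20, 100), 1)
        model = DepthModelSpec("poisson", 20.0, np.array([1.0]))
        r = ks_fitness(DepthObservations(d), model)
        assert 0 <= r.statistic <= 1 and 0 <= r.p_value <= 1

    def test_bimodal_depths_reject_single_poisson(self, rng):
        comp = rng.choice(2, size=5000, p=[0.6, 0.4])
        d = rng.poisson(30.0 * (comp + 1))
        obs = DepthObservations(d)
        fit = fit_single(obs, "poisson")
        assert ks_fitness(obs, fit.model).p_value < 1e-6

    def test_calibration_under_true_model(self):
        """Draws from the tested model itself: rejection rate near nominal."""
        model = DepthModelSpec("mixed_poisson", 30.0, np.array([0.85, 0.10, 0.05]))
        rejections = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            comp = r.choice(3, size=5000, p=model.weights)
            d = r.poisson(30.0 * (comp + 1))
            if ks_fitness(DepthObservations(d), model).p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / 200 <= 0.12


class TestBootstrap:
    def test_balance_exactness(self, rng):
        idx = balanced_bootstrap_indices(37, 100, rng)
        counts = np.bincount(idx.ravel(), minlength=37)
        assert (counts == 100).all()

    def test_constant_data_zero_sd(self, rng):
        obs = DepthObservations([9] * 60)
        res = bootstrap_em(obs, "mixed_poisson", EMConfig(M=1), B=10, seed=0)
        assert res.sd_C == 0.0 and (res.sd_weights == 0).all()

    def test_bootstrap_mean_near_point_estimate(self, rng):
        comp = rng.choice(3, size=4000, p=[0.85, 0.10, 0.05])
        d = rng.poisson(30.0 * (comp + 1))
        obs = DepthObservations(d)
        point = fit_em(obs, "mixed_poisson", EMConfig())
        res = bootstrap_em(obs, "mixed_poisson", EMConfig(), B=100, seed=1)
        assert abs(res.mean_C - point.model.C) < 2 * res.sd_C


@given(st.integers(2, 200), st.floats(1.0, 80.0))
def test_mixture_density_nonnegative_property(k, C):
    model = DepthModelSpec("mixed_poisson", C, np.array([0.8, 0.15, 0.05]))
    assert mixture_density(k, model) >= 0
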