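import math

import numpy as np
import pytest

import hergfit as hf
from hergfit.inference import (
    RateConstraint,
    adaptive_metropolis,
    adaptive_mcmc,
    cma_es_initialize,
    cma_es_minimize,
    log_likelihood,
    log_posterior,
    log_prior,
)


def _free_vector(problem, **overrides):
    from hergfit.synthetic import DEFAULT_TRUE_PARAMETERS

    values = {n: getattr(DEFAULT_TRUE_PARAMETERS, n) for n in problem.free_names}
    values.update(overrides)
    return np.array([values[n] for n in problem.free_names])


class TestRateConstraint:
    def test_defaults_admit_realistic_kinetics(self, truth):
        assert RateConstraint().satisfied(truth.params)

    def test_excessive_deactivation_rate_rejected(self, truth):
        # kC(-120) = 0.05 * exp(0.09 * 120) ≈ 2450 ms^-1 > 1000, although
        # both parameters sit inside the prior box.
        params = hf.RateParameters(**{**truth.params.__dict__, "kC1": 0.05, "kC2": 0.09})
        assert not RateConstraint().satisfied(params)

    def test_unachievably_slow_rate_rejected(self, truth):
        # kO never reaches 1.67e-5 anywhere in the window.
        params = hf.RateParameters(**{**truth.params.__dict__, "kO1": 2e-7, "kO2": 1e-7})
        assert not RateConstraint().satisfied(params)

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            RateConstraint(v_low=60.0, v_high=-120.0)
        with pytest.raises(ValueError):
            RateConstraint(rate_min=1.0, rate_max=0.5)


class TestLogLikelihood:
    def test_zero_residuals_give_normalisation_constant(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem)
        problem.observed = problem.simulate_currents(theta)
        sigma = problem.sigma_fixed
        n = problem.observed.size
        expected = -0.5 * n * math.log(2 * math.pi * sigma**2)
        assert log_likelihood(problem, theta) == pytest.approx(expected, abs=1e-12)

    def test_three_point_toy_matches_hand_evaluation(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem)
        keep_times, keep_obs = problem.times, problem.observed
        try:
            problem.times = problem.times[:3]
            problem._voltages = problem._voltages[:3]
            problem._driving_force = problem._driving_force[:3]
            residuals = np.array([0.01, -0.02, 0.00])
            problem.observed = problem.simulate_currents(theta) + residuals
            sigma = 0.00463
            expected = -1.5 * math.log(2 * math.pi * sigma**2) - float(
                residuals @ residuals
            ) / (2 * sigma**2)
            assert log_likelihood(problem, theta) == pytest.approx(expected, abs=1e-12)
        finally:
            problem.times, problem.observed = keep_times, keep_obs
            problem._voltages = problem.protocol.voltages(problem.times)
            problem._driving_force = problem._voltages - problem.constants.EK

    def test_likelihood_peaks_at_the_mle_noise_level(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem)
        predicted = problem.simulate_currents(theta)
        rng = np.random.default_rng(0)
        keep = problem.observed
        try:
            problem.observed = predicted + rng.normal(0.0, 0.01, predicted.size)
            residuals = problem.observed - predicted
            sigma_mle = float(np.sqrt(np.mean(residuals**2)))
            keep_sigma = problem.sigma_fixed

            def ll(sigma):
                problem.sigma_fixed = sigma
                return log_likelihood(problem, theta)

            try:
                assert ll(sigma_mle) > ll(sigma_mle / 2)
                assert ll(sigma_mle) > ll(sigma_mle * 2)
                assert ll(sigma_mle / 2) > ll(sigma_mle / 4)  # monotone below
            finally:
                problem.sigma_fixed = keep_sigma
        finally:
            problem.observed = keep


class TestLogPrior:
    def test_interior_point_gives_box_constant(self, coarse_problem, theta_truth):
        problem, _ = coarse_problem
        lower, upper = problem.free_bounds()
        expected = -float(np.sum(np.log(upper - lower)))
        assert log_prior(problem, theta_truth) == pytest.approx(expected)

    def test_conductance_above_prior_bound_rejected(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem, GKr=0.7)
        assert log_prior(problem, theta) == -np.inf

    def test_rate_constraint_violation_rejected_inside_box(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem, kC1=0.05, kC2=0.09)
        lower, upper = problem.free_bounds()
        assert np.all(theta >= lower) and np.all(theta <= upper)
        assert log_prior(problem, theta) == -np.inf

    def test_dimension_mismatch_raises(self, coarse_problem):
        problem, _ = coarse_problem
        with pytest.raises(ValueError):
            log_prior(problem, np.ones(3))


class TestLogPosterior:
    def test_rejected_point_runs_no_simulation(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem, GKr=5.0)
        before = problem.n_simulations
        assert log_posterior(problem, theta) == -np.inf
        assert problem.n_simulations == before

    def test_equals_sum_of_parts_on_interior_points(self, coarse_problem, theta_truth):
        problem, _ = coarse_problem
        rng = np.random.default_rng(42)
        for _ in range(10):
            theta = theta_truth * rng.uniform(0.95, 1.05, theta_truth.size)
            lp = log_prior(problem, theta)
            if not np.isfinite(lp):
                continue
            assert log_posterior(problem, theta) == pytest.approx(
                lp + log_likelihood(problem, theta), rel=1e-12
            )


class TestCmaEs:
    def test_recovers_quadratic_optimum_inside_box(self):
        rng_problem = np.random.default_rng(3)
        x_star = rng_problem.uniform(0.2, 0.8, 9)
        scales = rng_problem.uniform(0.5, 5.0, 9)

        def f(x):
            return float(np.sum(scales * (x - x_star) ** 2))

        result = cma_es_minimize(
            f, np.full(9, 0.5), 1 / 6, 4000, np.random.default_rng(0),
            lower=np.zeros(9), upper=np.ones(9),
        )
        assert np.abs(result.x_best - x_star).max() < 1e-3

    def test_single_restart_is_bit_reproducible(self, coarse_problem):
        problem, _ = coarse_problem
        a, _, _ = cma_es_initialize(problem, restarts=1, max_fevals=300, seed=7, n_screen=30)
        b, _, _ = cma_es_initialize(problem, restarts=1, max_fevals=300, seed=7, n_screen=30)
        np.testing.assert_array_equal(a, b)

    def test_start_point_beats_random_prior_draws(self, coarse_problem):
        problem, _ = coarse_problem
        theta0, _, _ = cma_es_initialize(problem, restarts=1, max_fevals=500, seed=11)
        lp0 = log_posterior(problem, theta0)
        lower, upper = problem.free_bounds()
        rng = np.random.default_rng(100)
        draws = rng.uniform(lower, upper, size=(1000, problem.n_free))
        assert all(log_posterior(problem, d) <= lp0 for d in draws)


class TestAdaptiveMetropolis:
    def test_recovers_two_dimensional_gaussian(self):
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)

        def target(x):
            d = x - mean
            return -0.5 * float(d @ prec @ d)

        chain, _, acc = adaptive_metropolis(
            target, np.zeros(2), 20000, 5000, np.random.default_rng(0), np.eye(2)
        )
        est_mean = chain.mean(axis=0)
        est_cov = np.cov(chain.T)
        # batch-means Monte-Carlo standard error
        batches = chain.reshape(30, -1, 2).mean(axis=1)
        se = batches.std(axis=0, ddof=1) / math.sqrt(len(batches))
        assert np.all(np.abs(est_mean - mean) < 3 * se)
        assert np.linalg.norm(est_cov - cov) < 0.10 * np.linalg.norm(cov)
        assert 0.1 < acc < 0.5

    def test_flat_bounded_target_samples_uniformly(self):
        from scipy.stats import kstest

        def target(x):
            return 0.0 if 0.0 <= x[0] <= 1.0 else -np.inf

        chain, _, _ = adaptive_metropolis(
            target, np.array([0.5]), 30000, 10000, np.random.default_rng(0),
            np.array([[0.01]]),
        )
        thinned = chain[::30, 0]  # reduce autocorrelation before the KS test
        assert kstest(thinned, "uniform").pvalue > 0.01

    def test_infinite_start_rejected(self):
        with pytest.raises(ValueError):
            adaptive_metropolis(
                lambda x: -np.inf, np.zeros(1), 100, 10, np.random.default_rng(0), np.eye(1)
            )


class TestAdaptiveMcmcOnProblem:
    def test_retained_samples_stay_in_support(self, coarse_problem, theta_truth):
        problem, _ = coarse_problem
        sample = adaptive_mcmc(problem, theta_truth, num_iters=500, burn=100, seed=5)
        lower, upper = problem.free_bounds()
        assert np.all(sample.chain >= lower) and np.all(sample.chain <= upper)
        assert np.all(np.isfinite(sample.log_posteriors))
        for theta in sample.chain[::50]:
            assert problem.rate_constraint.satisfied(problem.rate_parameters(theta))
        assert 0.0 < sample.acceptance_rate < 1.0

    def test_identical_seed_gives_bit_identical_chain(self, coarse_problem, theta_truth):
        problem, _ = coarse_problem
        a = adaptive_mcmc(problem, theta_truth, num_iters=300, burn=50, seed=9)
        b = adaptive_mcmc(problem, theta_truth, num_iters=300, burn=50, seed=9)
        np.testing.assert_array_equal(a.chain, b.chain)
        np.testing.assert_array_equal(a.log_posteriors, b.log_posteriors)

    def test_invalid_iteration_counts_rejected(self, coarse_problem, theta_truth):
        problem, _ = coarse_problem
        with pytest.raises(ValueError):
            adaptive_mcmc(problem, theta_truth, num_iters=100, burn=100, seed=1)

    def test_zero_probability_start_rejected(self, coarse_problem):
        problem, _ = coarse_problem
        theta = _free_vector(problem, GKr=5.0)
        with pytest.raises(ValueError):
            adaptive_mcmc(problem, theta, num_iters=100, burn=10, seed=1)
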