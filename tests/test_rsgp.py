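"""Reward-sensitive GP: kernels, conditionals, likelihood, fitting, decomposition."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import rsgp_timing as rt
from rsgp_timing import rsgp
from rsgp_timing.rsgp import (
    RSGPParams,
    _nll_and_grad,
    build_cov,
    fit_mml,
    forward_simulate,
    infer_e_slow,
    k_se,
    log_marginal_likelihood,
    sample_next,
)


class TestKernel:
    @pytest.mark.parametrize(
        "r, l, expected",
        [
            (0, 5.0, 1.0),
            (5, 5.0, np.exp(-0.5)),
            (60, 20.0, np.exp(-4.5)),
        ],
    )
    def test_squared_exponential_closed_form(self, r, l, expected):
        assert k_se(r, l) == pytest.approx(expected)

    def test_invalid_length_scale(self):
        with pytest.raises(ValueError):
            k_se(1, 0.0)


class TestBuildCov:
    def test_hand_computed_three_trial_example(self):
        """Cross-covariances to trial 3 gate on the earlier trial's reward."""
        p = RSGPParams(l_se=2.0, sigma_se=1.0, l_rs=1.0, sigma_rs=1.0, sigma_0=1e-9)
        K = build_cov(p, [True, False, False]).values
        assert K[2, 0] == pytest.approx(np.exp(-4 / 8) + np.exp(-4 / 2))
        assert K[2, 1] == pytest.approx(np.exp(-1 / 8) + 0.0)

    def test_all_unrewarded_reduces_rs_to_identity(self):
        p = RSGPParams(20.0, 0.141, 2.0, 0.141, 0.1)
        K = build_cov(p, [False] * 6).values
        lags = np.subtract.outer(np.arange(6), np.arange(6))
        expected = (
            p.sigma_se**2 * np.exp(-(lags**2) / (2 * p.l_se**2))
            + (p.sigma_rs**2 + p.sigma_0**2) * np.eye(6)
        )
        np.testing.assert_allclose(K, expected)

    def test_diagonal_is_total_variance(self):
        p = RSGPParams(20.0, 0.141, 2.0, 0.141, 0.1)
        K = build_cov(p, [True, False, True, True]).values
        np.testing.assert_allclose(np.diag(K), p.total_variance)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            RSGPParams(20.0, -0.1, 2.0, 0.1, 0.1)

    def test_psd_at_realistic_hyperparameters(self, ground_truth, rng):
        """Every reward mask yields a (numerically) PSD covariance at the
        reference hyperparameters."""
        for _ in range(25):
            n = int(rng.integers(2, 60))
            mask = rng.random(n) < rng.random()
            cov = build_cov(ground_truth, mask)
            tol = 1e-8 * np.trace(cov.values) / n
            assert cov.min_eigenvalue() >= -tol


class TestSampleNext:
    def test_empty_history_prior_variance(self, ground_truth, rng):
        mu, var, _ = sample_next([], [], ground_truth, rng)
        assert mu == 0.0
        assert var == pytest.approx(ground_truth.total_variance)

    def test_matches_bivariate_conditional_without_reward_kernel(self, rng):
        """With sigma_RS = 0 the conditional is the textbook SE-GP formula."""
        p = RSGPParams(3.0, 0.2, 2.0, 0.0, 0.1)
        e_prev = 0.13
        mu, var, _ = sample_next([e_prev], [False], p, rng)
        k01 = p.sigma_se**2 * np.exp(-1 / (2 * p.l_se**2))
        k00 = p.total_variance
        assert mu == pytest.approx(k01 / k00 * e_prev, rel=1e-6)
        assert var == pytest.approx(k00 - k01**2 / k00, rel=1e-5)

    def test_reward_tightens_the_conditional(self, ground_truth, rng):
        """A rewarded previous trial increases cross-covariance and therefore
        shrinks the next trial's conditional variance."""
        _, var_rew, _ = sample_next([0.05], [True], ground_truth, rng)
        _, var_unrew, _ = sample_next([0.05], [False], ground_truth, rng)
        assert var_rew < var_unrew

    def test_reward_locality(self, ground_truth, rng):
        """Toggling the reward label of a trial more than 5 l_RS in the past
        barely changes the next conditional variance."""
        n = 40  # lag 40 > 5 * l_RS = 10
        e = list(0.05 * rng.standard_normal(n))
        base = [False] * n
        far = [True] + [False] * (n - 1)
        _, v0, _ = sample_next(e, base, ground_truth, rng)
        _, v1, _ = sample_next(e, far, ground_truth, rng)
        assert abs(v1 - v0) < 1e-6 * ground_truth.total_variance


class TestLogMarginalLikelihood:
    def test_single_trial_univariate_gaussian(self, ground_truth):
        e = np.array([0.21])
        v = ground_truth.total_variance
        expected = -0.5 * (np.log(2 * np.pi) + np.log(v) + 0.21**2 / v)
        got = log_marginal_likelihood(ground_truth, e, [False], center=False)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_matches_brute_force_density_n5(self, rng):
        p = RSGPParams(2.0, 0.3, 1.0, 0.2, 0.15)
        e = rng.normal(0, 0.2, 5)
        rew = [True, False, True, True, False]
        K = build_cov(p, rew).values
        x = e - e.mean()
        oracle = multivariate_normal(np.zeros(5), K).logpdf(x)
        assert log_marginal_likelihood(p, e, rew) == pytest.approx(oracle, abs=1e-5)

    def test_permutation_invariant_when_iid(self, rng):
        p = RSGPParams(20.0, 1e-4, 2.0, 1e-4, 0.12)
        e = rng.normal(0, 0.1, 30)
        rew = rng.random(30) < 0.5
        a = log_marginal_likelihood(p, e, rew)
        perm = rng.permutation(30)
        b = log_marginal_likelihood(p, e[perm], rew[perm])
        assert a == pytest.approx(b, abs=1e-3)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        theta = np.array([5.0, 0.25, 1.5, 0.18, 0.12])
        e = rng.normal(0, 0.2, 50)
        rew = rng.random(50) < 0.5
        x = e - e.mean()
        free = np.ones(5, bool)
        z = np.log(theta)
        _, g = _nll_and_grad(z, x, rew, free, theta.copy())
        for i in range(5):
            dz = np.zeros(5)
            dz[i] = 1e-6
            fp, _ = _nll_and_grad(z + dz, x, rew, free, theta.copy())
            fm, _ = _nll_and_grad(z - dz, x, rew, free, theta.copy())
            assert g[i] == pytest.approx((fp - fm) / 2e-6, rel=1e-4, abs=1e-6)

    def test_generating_parameters_beat_perturbed_ones(self, ground_truth):
        """On average over seeds, the likelihood at the generating
        hyperparameters exceeds the likelihood after a x4 perturbation of any
        single hyperparameter."""
        wins = np.zeros(5)
        n_seeds = 4
        for seed in range(n_seeds):
            sim = forward_simulate(ground_truth, 300, seed=seed, window_rel=0.12)
            df = sim.to_frame()
            e, rew = df["e"].to_numpy(), df["rewarded"].to_numpy(bool)
            ll0 = log_marginal_likelihood(ground_truth, e, rew)
            base = ground_truth.as_array()
            for i in range(5):
                pert = base.copy()
                pert[i] *= 4.0
                try:
                    ll1 = log_marginal_likelihood(RSGPParams.from_array(pert), e, rew)
                except np.linalg.LinAlgError:
                    ll1 = -np.inf  # indefinite covariance: infinitely worse
                wins[i] += ll0 > ll1
        assert (wins > n_seeds / 2).all()


class TestForwardSimulate:
    def test_pure_noise_is_iid(self):
        p = RSGPParams(20.0, 1e-6, 2.0, 1e-6, 0.1)
        sim = forward_simulate(p, 800, seed=4)
        e = sim.to_frame()["e"].to_numpy()
        assert e.std() == pytest.approx(0.1, rel=0.1)
        assert abs(np.corrcoef(e[:-1], e[1:])[0, 1]) < 0.08

    def test_deterministic_under_seed(self, ground_truth):
        a = forward_simulate(ground_truth, 100, seed=9)
        b = forward_simulate(ground_truth, 100, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_rejects_empty_run(self, ground_truth):
        with pytest.raises(ValueError):
            forward_simulate(ground_truth, 0)


class TestFitMML:
    def test_refit_without_reward_kernel(self):
        """Data generated with sigma_RS = 0 comes back with a negligible
        reward-kernel variance share (the MLE of a boundary parameter is
        biased upward at finite n, so the share, not the raw value, is the
        meaningful quantity)."""
        p = RSGPParams(20.0, 0.141, 2.0, 1e-4, 0.1)
        sim = forward_simulate(p, 1000, seed=21, window_rel=0.12)
        df = sim.to_frame()
        fit = fit_mml(df["e"].to_numpy(), df["rewarded"].to_numpy(bool), restarts=2, seed=0)
        assert fit.sigma_rs**2 / fit.total_variance < 0.05
        assert fit.sigma_rs < fit.sigma_se / 3

    def test_iid_data_attributes_variance_to_noise(self, rng):
        e = rng.normal(0.0, 0.1, 500)
        rew = rng.random(500) < 0.5
        fit = fit_mml(e, rew, restarts=1, seed=0)
        assert fit.sigma_se < 0.03
        assert fit.sigma_0 == pytest.approx(0.1, rel=0.15)

    def test_single_outcome_falls_back_with_warning(self, rng):
        e = rng.normal(0.0, 0.1, 120)
        with pytest.warns(UserWarning, match="single-step"):
            fit_mml(e, np.ones(120, bool), restarts=1, seed=0)


class TestInferESlow:
    def test_pure_slow_model_returns_series(self, rng):
        """With sigma_RS ~ sigma_0 ~ 0 the slow component is the whole signal."""
        p = RSGPParams(10.0, 0.2, 2.0, 1e-6, 1e-6)
        sim = forward_simulate(p, 200, seed=2)
        df = sim.to_frame()
        dec = infer_e_slow(df["e"].to_numpy(), p, df["rewarded"].to_numpy(bool))
        np.testing.assert_allclose(dec.e_slow, df["e"], atol=1e-4)

    def test_iid_fit_gives_flat_slow_component(self, rng):
        e = rng.normal(0.3, 0.1, 300)
        rew = rng.random(300) < 0.5
        p = RSGPParams(20.0, 1e-4, 2.0, 1e-4, 0.1)
        dec = infer_e_slow(e, p, rew)
        assert np.ptp(dec.e_slow) < 0.01
        assert dec.e_slow.mean() == pytest.approx(e.mean(), abs=1e-3)

    def test_recovers_planted_slow_component(self, rng):
        """Slow GP + iid noise: the posterior slow component correlates > 0.9
        with the planted drift at n = 1000."""
        n = 1000
        lags = np.subtract.outer(np.arange(n), np.arange(n))
        Kse = 0.141**2 * np.exp(-(lags**2) / (2 * 20.0**2))
        slow = rng.multivariate_normal(np.zeros(n), Kse + 1e-10 * np.eye(n))
        e = slow + 0.1 * rng.standard_normal(n)
        p = RSGPParams(20.0, 0.141, 2.0, 1e-6, 0.1)
        dec = infer_e_slow(e, p, np.zeros(n, bool))
        assert np.corrcoef(dec.e_slow, slow)[0, 1] > 0.9

    def test_decomposition_sums_to_signal(self, rsgp_session, ground_truth):
        dec = infer_e_slow(rsgp_session, ground_truth, context="ES")
        e = rsgp_session.context_subset("ES")["e"].to_numpy()
        np.testing.assert_allclose(dec.e_slow + dec.e_fast, e, atol=1e-10)
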