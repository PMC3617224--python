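"""Maximum-likelihood machinery: per-trial likelihoods and the MLE driver."""

import numpy as np
import pytest
from scipy.special import expit, logit

from deltadiag.agents import AgentConfig, simulate_bandit_session, simulate_estimation_session
from deltadiag.fitting import (
    fit_mle,
    trial_logliks_bayes,
    trial_logliks_fixed,
    wald_ci,
)
from deltadiag.tasks import generate_bandit_schedule, generate_changepoint_series


class TestTrialLogliksFixed:
    def test_bandit_beta_zero_all_log_quarter(self, bandit_session_fixed):
        ll = trial_logliks_fixed(0.3, 0.0, bandit_session_fixed)
        assert np.allclose(ll, np.log(0.25))

    def test_bandit_probabilities_normalize_per_trial(self, bandit_session_fixed):
        """Exp of the per-option log-probabilities sums to one on every
        trial of the replayed value trajectory."""
        from deltadiag.agents import log_softmax
        from deltadiag.fitting import _replay_fixed_bandit

        s = bandit_session_fixed
        qmat = _replay_fixed_bandit(s.responses, s.outcomes, 0.3, 4)
        probs = np.exp(log_softmax(5.0 * qmat, axis=1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        # the lam=0 generative trajectory is the replayed one
        assert np.allclose(qmat, s.estimates, atol=1e-12)

    def test_estimation_loglik_upper_bounded_by_zero(self, est_session_fixed):
        ll = trial_logliks_fixed(0.3, 2.0, est_session_fixed)
        assert np.all(ll < 0)

    def test_likelihood_dominance_at_true_parameters(self):
        """Averaged over sessions, the generative (alpha, beta) beats
        perturbed learning rates."""
        series = [generate_changepoint_series(400, seed=60 + i) for i in range(6)]
        sessions = [
            simulate_estimation_session(s, AgentConfig(0.4, 0.0, 2.0, seed=70 + i))
            for i, s in enumerate(series)
        ]
        def total(alpha):
            return sum(trial_logliks_fixed(alpha, 2.0, s).sum() for s in sessions)

        assert total(0.4) > total(0.2)
        assert total(0.4) > total(0.6)

    def test_response_outside_grid_raises(self, est_session_fixed):
        import dataclasses

        bad = dataclasses.replace(
            est_session_fixed,
            responses=est_session_fixed.responses.copy(),
        )
        bad.responses[0] = 400.0
        with pytest.raises(ValueError):
            trial_logliks_fixed(0.3, 2.0, bad)

    @pytest.mark.parametrize("alpha,beta", [(-0.1, 1.0), (1.1, 1.0), (0.5, -1.0)])
    def test_invalid_parameters_raise(self, est_session_fixed, alpha, beta):
        with pytest.raises(ValueError):
            trial_logliks_fixed(alpha, beta, est_session_fixed)


class TestTrialLogliksBayes:
    def test_bandit_beta_zero_all_log_quarter(self, bandit_session_adaptive):
        ll = trial_logliks_bayes(0.0, bandit_session_adaptive)
        assert np.allclose(ll, np.log(0.25))

    def test_deterministic_repeated_evaluation(self, est_session_adaptive):
        a = trial_logliks_bayes(2.0, est_session_adaptive)
        b = trial_logliks_bayes(2.0, est_session_adaptive)
        assert np.array_equal(a, b)

    def test_beta_recovery_from_adaptive_agent(self):
        """Fitting the adaptive model to lam=1 sessions recovers the
        generative inverse temperature within 15%."""
        series = [generate_changepoint_series(800, seed=80 + i) for i in range(6)]
        sessions = [
            simulate_estimation_session(s, AgentConfig(0.3, 1.0, 2.0, seed=90 + i))
            for i, s in enumerate(series)
        ]
        fit = fit_mle("bayes_lr", sessions, seed=2)
        assert fit.params["beta"] == pytest.approx(2.0, rel=0.15)


class TestFitMLE:
    def test_recovery_lam_zero_estimation(self):
        series = [generate_changepoint_series(800, seed=100 + i) for i in range(6)]
        sessions = [
            simulate_estimation_session(s, AgentConfig(0.3, 0.0, 2.0, seed=110 + i))
            for i, s in enumerate(series)
        ]
        fit = fit_mle("fixed_lr", sessions, seed=3)
        assert fit.converged
        assert fit.params["alpha"] == pytest.approx(0.3, abs=0.05)
        lo, hi = wald_ci(fit, "beta")
        assert lo < 2.0 < hi

    def test_gradient_numerically_zero_at_optimum(self, bandit_session_fixed):
        """Central-difference gradient of the pooled log-likelihood in
        transformed coordinates vanishes at the returned optimum."""
        fit = fit_mle("fixed_lr", bandit_session_fixed, seed=4)
        a, b = fit.params["alpha"], fit.params["beta"]

        def neg_loglik(theta):
            return -trial_logliks_fixed(
                float(expit(theta[0])), float(np.exp(theta[1])), bandit_session_fixed
            ).sum()

        theta = np.array([logit(a), np.log(b)])
        h = 1e-5
        grad = []
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            grad.append((neg_loglik(theta + e) - neg_loglik(theta - e)) / (2 * h))
        assert np.max(np.abs(grad)) < 1e-4

    def test_more_restarts_never_worse(self, bandit_session_adaptive):
        f10 = fit_mle("fixed_lr", bandit_session_adaptive, n_restarts=10, seed=5)
        f20 = fit_mle("fixed_lr", bandit_session_adaptive, n_restarts=20, seed=5)
        assert f20.loglik >= f10.loglik - 1e-6

    def test_all_excluded_raises(self, bandit_session_fixed):
        mask = np.zeros(bandit_session_fixed.n_trials, dtype=bool)
        with pytest.raises(ValueError):
            fit_mle("fixed_lr", bandit_session_fixed, include_masks=[mask])

    def test_mask_length_mismatch_raises(self, bandit_session_fixed):
        with pytest.raises(ValueError):
            fit_mle(
                "fixed_lr",
                bandit_session_fixed,
                include_masks=[np.ones(10, dtype=bool)],
            )

    def test_mixed_task_kinds_raise(self, bandit_session_fixed, est_session_fixed):
        with pytest.raises(ValueError):
            fit_mle("fixed_lr", [bandit_session_fixed, est_session_fixed])

    def test_unknown_model_raises(self, bandit_session_fixed):
        with pytest.raises(ValueError):
            fit_mle("extra_lr", bandit_session_fixed)

    def test_information_criteria_consistency(self, bandit_session_fixed):
        fit = fit_mle("fixed_lr", bandit_session_fixed, seed=6)
        k, n = 2, bandit_session_fixed.n_trials
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(k * np.log(n) - 2 * fit.loglik)

    def test_covariance_positive_semidefinite(self, bandit_session_fixed):
        fit = fit_mle("fixed_lr", bandit_session_fixed, seed=7)
        assert fit.converged
        eigs = np.linalg.eigvalsh(fit.covariance)
        assert np.all(eigs >= -1e-12)

    def test_null_model_closed_form(self, bandit_session_fixed):
        fit = fit_mle("null", bandit_session_fixed)
        n = bandit_session_fixed.n_trials
        assert fit.loglik == pytest.approx(n * np.log(0.25))
        assert fit.aic == fit.bic == pytest.approx(-2 * n * np.log(0.25))

    def test_deterministic_given_seed(self, bandit_session_adaptive):
        f1 = fit_mle("fixed_lr", bandit_session_adaptive, seed=8)
        f2 = fit_mle("fixed_lr", bandit_session_adaptive, seed=8)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_exclusion_changes_n_obs(self, bandit_session_fixed):
        mask = np.ones(bandit_session_fixed.n_trials, dtype=bool)
        mask[:100] = False
        fit = fit_mle("fixed_lr", bandit_session_fixed, include_masks=[mask], seed=9)
        assert fit.n_obs == bandit_session_fixed.n_trials - 100
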