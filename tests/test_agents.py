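"""Agent primitives and session simulators.

The reduced Bayesian observer is checked against an independent
two-hypothesis Bayes-rule oracle written directly with scipy densities,
and the adaptiveness blend is checked for exact endpoint equivalence
with an independently coded fixed-rate delta rule.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from deltadiag.agents import (
    AgentConfig,
    BeliefState,
    blend_learning_rate,
    delta_update,
    prediction_grid,
    reduced_bayes_step,
    simulate_bandit_session,
    simulate_estimation_session,
    softmax_probs,
)
from deltadiag.tasks import generate_bandit_schedule, generate_changepoint_series


def oracle_two_hypothesis(estimate, run_length, outcome, hazard, sd, lo, hi):
    """Independent change-point posterior: Bayes rule over the two
    hypotheses, written with scipy distribution objects."""
    p_change = hazard * stats.uniform(lo, hi - lo).pdf(outcome)
    sigma_pred = sd * np.sqrt(1.0 + 1.0 / run_length)
    p_stay = (1.0 - hazard) * stats.norm(estimate, sigma_pred).pdf(outcome)
    omega = p_change / (p_change + p_stay)
    alpha = omega + (1.0 - omega) / (run_length + 1.0)
    return omega, alpha


class TestDeltaUpdate:
    def test_midpoint(self):
        assert delta_update(100.0, 140.0, 0.5) == 120.0

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    def test_zero_rate_keeps_estimate(self, e, x):
        assert delta_update(e, x, 0.0) == e

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    def test_unit_rate_jumps_to_outcome(self, e, x):
        # e + 1*(x - e) cancels to x only up to floating-point rounding
        assert delta_update(e, x, 1.0) == pytest.approx(x, abs=1e-9)

    @pytest.mark.parametrize("rate", [-0.01, 1.01])
    def test_rate_out_of_bounds(self, rate):
        with pytest.raises(ValueError):
            delta_update(0.0, 1.0, rate)


class TestBlend:
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_endpoints(self, af, ab):
        assert blend_learning_rate(af, ab, 0.0) == af
        assert blend_learning_rate(af, ab, 1.0) == ab

    def test_midpoint(self):
        assert blend_learning_rate(0.2, 0.8, 0.5) == pytest.approx(0.5)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_stays_in_unit_interval(self, af, ab, lam):
        assert 0.0 <= blend_learning_rate(af, ab, lam) <= 1.0


class TestSoftmax:
    def test_beta_zero_uniform(self):
        p = softmax_probs(np.array([3.0, -1.0, 0.5, 2.0]), 0.0)
        assert np.allclose(p, 0.25)

    def test_closed_form_two_values(self):
        p = softmax_probs(np.array([1.0, 0.0]), 1.0)
        e = np.e
        assert np.allclose(p, [e / (e + 1), 1 / (e + 1)], atol=1e-12)

    def test_large_beta_concentrates_on_argmax(self):
        p = softmax_probs(np.array([1.0, 0.9, 0.2]), 1e4)
        assert p[0] > 0.999

    def test_overflow_safe(self):
        p = softmax_probs(np.array([1e4, 0.0]), 100.0)
        assert np.isfinite(p).all() and abs(p.sum() - 1.0) < 1e-12

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.floats(0, 20),
        st.floats(0, 20),
    )
    def test_top_value_probability_nondecreasing_in_beta(self, values, b1, b2):
        values = np.asarray(values)
        lo, hi = sorted((b1, b2))
        i = int(np.argmax(values))
        assert softmax_probs(values, hi)[i] >= softmax_probs(values, lo)[i] - 1e-12

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            softmax_probs(np.array([]), 1.0)


class TestReducedBayes:
    def test_matches_independent_bayes_oracle_on_grid(self):
        """Omega and alpha agree with the scipy-based two-hypothesis
        calculation to 1e-10 over a 1000-point state/outcome grid."""
        lo, hi, sd, hazard = 0.0, 300.0, 20.0, 0.1
        estimates = np.linspace(10, 290, 10)
        run_lengths = np.array([0.5, 1, 2, 5, 10, 25, 50, 100, 200, 400])
        outcomes = np.linspace(0, 300, 10)
        for e in estimates:
            for r in run_lengths:
                for x in outcomes:
                    new = reduced_bayes_step(
                        BeliefState(estimate=e, run_length=r), x, hazard, sd, (lo, hi)
                    )
                    om, al = oracle_two_hypothesis(e, r, x, hazard, sd, lo, hi)
                    assert new.cp_prob == pytest.approx(om, abs=1e-10)
                    assert new.current_alpha == pytest.approx(al, abs=1e-10)

    def test_spec_point_example(self):
        new = reduced_bayes_step(
            BeliefState(estimate=150.0, run_length=5.0), 10.0, 0.1, 20.0, (0.0, 300.0)
        )
        om, al = oracle_two_hypothesis(150.0, 5.0, 10.0, 0.1, 20.0, 0.0, 300.0)
        assert new.cp_prob == pytest.approx(om, abs=1e-10)
        assert new.current_alpha == pytest.approx(al, abs=1e-10)

    def test_zero_hazard_running_average(self):
        new = reduced_bayes_step(
            BeliefState(estimate=100.0, run_length=4.0), 120.0, 0.0, 20.0, (0.0, 300.0)
        )
        assert new.cp_prob == 0.0
        assert new.current_alpha == pytest.approx(1.0 / 5.0)
        assert new.run_length == pytest.approx(5.0)

    def test_unsurprising_outcome_small_alpha(self):
        new = reduced_bayes_step(
            BeliefState(estimate=150.0, run_length=50.0), 150.0, 0.01, 20.0, (0.0, 300.0)
        )
        assert new.cp_prob < 0.05
        assert new.current_alpha == pytest.approx(1.0 / 51.0, abs=0.02)

    def test_omega_increasing_in_error_magnitude(self):
        omegas = [
            reduced_bayes_step(
                BeliefState(estimate=150.0, run_length=10.0),
                150.0 + d,
                0.1,
                20.0,
                (0.0, 300.0),
            ).cp_prob
            for d in np.linspace(0, 140, 15)
        ]
        assert np.all(np.diff(omegas) > 0)

    def test_full_detection_resets_run_length_toward_one(self):
        new = reduced_bayes_step(
            BeliefState(estimate=150.0, run_length=200.0), 0.5, 0.5, 5.0, (0.0, 300.0)
        )
        assert new.cp_prob > 0.99
        assert new.run_length < 3.0


class TestEstimationSession:
    def test_lam_zero_realized_alphas_constant(self, est_session_fixed):
        assert np.allclose(est_session_fixed.realized_alphas, 0.3)

    def test_estimate_recursion_invariant(self, est_session_adaptive):
        s = est_session_adaptive
        expected = s.estimates[:-1] + s.realized_alphas[:-1] * (
            s.outcomes[:-1] - s.estimates[:-1]
        )
        assert np.allclose(s.estimates[1:], expected, atol=1e-9)

    def test_lam_zero_path_equals_independent_fixed_reference(self, small_series):
        """A lam=0 adaptive agent's estimate path must coincide with a
        straightforwardly coded fixed-rate delta rule to 1e-12."""
        agent = AgentConfig(alpha_fixed=0.37, adaptiveness=0.0, beta=1.0, seed=5)
        rec = simulate_estimation_session(small_series, agent)
        e, ref = 150.0, []
        for x in small_series.outcomes:
            ref.append(e)
            e = e + 0.37 * (x - e)
        assert np.max(np.abs(rec.estimates - np.asarray(ref))) < 1e-12

    def test_win_stay_limit(self, small_series):
        """With alpha=1, lam=0 and near-deterministic responding, each
        prediction equals the previous outcome rounded to the grid."""
        agent = AgentConfig(alpha_fixed=1.0, adaptiveness=0.0, beta=1e6, seed=7)
        rec = simulate_estimation_session(small_series, agent)
        expected = np.round(small_series.outcomes[:-1])
        assert np.array_equal(rec.responses[1:], expected)

    def test_alphas_in_unit_interval_for_all_lams(self, small_series):
        for lam in (0.0, 0.3, 0.7, 1.0):
            rec = simulate_estimation_session(
                small_series, AgentConfig(adaptiveness=lam, beta=1.0, seed=11)
            )
            assert np.all((rec.realized_alphas >= 0) & (rec.realized_alphas <= 1))

    def test_adaptive_alphas_lower_median_wider_iqr(
        self, est_session_fixed, est_session_adaptive
    ):
        a0 = est_session_fixed.realized_alphas
        a1 = est_session_adaptive.realized_alphas
        assert np.median(a1) < np.median(a0)
        iqr = lambda a: np.subtract(*np.percentile(a, [75, 25]))
        assert iqr(a1) > iqr(a0)

    def test_response_mode_at_grid_point_nearest_estimate(self):
        """The soft-max response distribution peaks at the grid point
        closest to the current estimate."""
        grid = prediction_grid((0.0, 300.0))
        for e in (17.3, 149.6, 150.49, 283.9):
            utilities = -((grid - e) ** 2) / (2 * 20.0**2)
            probs = softmax_probs(utilities, 2.0)
            assert grid[np.argmax(probs)] == np.round(e)

    def test_reproducible(self, small_series):
        a = simulate_estimation_session(small_series, AgentConfig(seed=3))
        b = simulate_estimation_session(small_series, AgentConfig(seed=3))
        assert np.array_equal(a.responses, b.responses)
        assert np.array_equal(a.estimates, b.estimates)


class TestBanditSession:
    def test_beta_zero_choice_frequencies_uniform(self):
        sched = generate_bandit_schedule(10_000, seed=31)
        agent = AgentConfig(
            alpha_fixed=0.3, beta=0.0, assumed_hazard=0.04,
            assumed_noise_sd=0.2, seed=37,
        )
        rec = simulate_bandit_session(sched, agent)
        counts = np.bincount(rec.responses, minlength=4)
        lo = stats.binom.ppf(0.005, 10_000, 0.25)
        hi = stats.binom.ppf(0.995, 10_000, 0.25)
        assert np.all((counts >= lo) & (counts <= hi))

    def test_lam_zero_realized_alpha_constant(self, bandit_session_fixed):
        assert np.allclose(bandit_session_fixed.realized_alphas, 0.3)

    def test_only_chosen_arm_updates(self, bandit_session_fixed):
        s = bandit_session_fixed
        for t in range(s.n_trials - 1):
            unchosen = [a for a in range(4) if a != s.responses[t]]
            assert np.array_equal(s.estimates[t + 1, unchosen], s.estimates[t, unchosen])

    def test_adaptive_alpha_spikes_after_changepoints(self, bandit_session_adaptive):
        s = bandit_session_adaptive
        offsets = np.empty(s.n_trials, dtype=int)
        last = -1
        for t in range(s.n_trials):
            if s.environment.is_change[t]:
                last = t
            offsets[t] = t - last
        early = s.realized_alphas[(offsets >= 1) & (offsets <= 3)]
        late = s.realized_alphas[offsets >= 10]
        assert early.mean() > late.mean()

    def test_alphas_in_unit_interval(self, bandit_session_adaptive):
        a = bandit_session_adaptive.realized_alphas
        assert np.all((a >= 0) & (a <= 1))


class TestAgentConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_fixed": 1.2},
            {"adaptiveness": -0.1},
            {"beta": -1.0},
            {"assumed_hazard": 1.5},
            {"assumed_noise_sd": 0.0},
        ],
    )
    def test_invalid_raises(self, kwargs):
        with pytest.raises(ValueError):
            AgentConfig(**kwargs)
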