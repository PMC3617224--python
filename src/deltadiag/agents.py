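"""Learning agents: fixed delta rule through reduced Bayesian observer.

The generative agent used throughout the package is a delta rule

    E <- E + alpha_t * (outcome - E)

whose per-trial learning rate ``alpha_t`` interpolates between a fixed
value and the learning rate of a reduced Bayesian change-point observer:

    alpha_t = (1 - lam) * alpha_fixed + lam * alpha_bayes_t

with ``lam`` ("adaptiveness") in [0, 1].  At ``lam = 0`` the update path
is exactly a fixed-learning-rate delta rule; at ``lam = 1`` it is the
reduced Bayesian observer.

The reduced Bayesian observer tracks a point estimate ``E`` and an
expected run length ``r`` (trials since the last inferred change-point).
After each outcome it computes a change-point probability ``omega`` by a
two-hypothesis Bayes rule — "a change happened" (outcome from a uniform
density on the outcome range) versus "no change" (outcome from a
Gaussian predictive centered at ``E`` with variance
``sigma**2 * (1 + 1/r)``) — and sets

    alpha_bayes = omega + (1 - omega) / (r + 1)
    r'          = (r + 1) * (1 - omega) + omega

so surprisingly large prediction errors transiently drive the learning
rate toward one while long stable runs drive it toward zero.

Action selection is soft-max in both tasks.  In the bandit task choices
are soft-max over per-arm value estimates with inverse temperature
``beta``.  In the estimation task the emitted prediction is a soft-max
draw over the integer grid of the outcome range with quadratic utility
``-(p - E)**2 / (2 * sigma**2)``, i.e. a discretized Gaussian centered
on the current estimate with response noise controlled by ``beta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tasks import BanditSchedule, ChangePointSeries

__all__ = [
    "AgentConfig",
    "BeliefState",
    "SessionRecord",
    "delta_update",
    "reduced_bayes_step",
    "blend_learning_rate",
    "softmax_probs",
    "log_softmax",
    "simulate_estimation_session",
    "simulate_bandit_session",
]

#: Initial value estimate for each bandit arm (uninformative midpoint of
#: the Bernoulli reward range); also used when replaying fitted models.
BANDIT_Q_INIT = 0.5

#: Floor on the assumed outcome SD in the bandit change-point machinery.
#: Rewards are Bernoulli, so the observer's Gaussian predictive uses the
#: belief-dependent variance Q*(1-Q), floored at this value squared so
#: near-certain beliefs cannot make the predictive density degenerate.
DEFAULT_BANDIT_NOISE_SD = 0.2

#: Initial expected run length.  r = 1 makes the very first update a
#: half-weight average and keeps the Gaussian predictive variance finite.
INITIAL_RUN_LENGTH = 1.0


@dataclass
class AgentConfig:
    """Generative agent parameters.

    alpha_fixed : learning rate of the non-adaptive component, in [0, 1].
    adaptiveness : blend weight ``lam`` in [0, 1]; 0 = pure fixed delta
        rule, 1 = reduced Bayesian observer.
    beta : soft-max inverse temperature (>= 0); high = exploitative.
    assumed_hazard : hazard rate the observer assumes.
    assumed_noise_sd : outcome noise SD the observer assumes; also sets
        the width of the estimation-task response distribution.
    """

    alpha_fixed: float = 0.3
    adaptiveness: float = 0.0
    beta: float = 1.0
    assumed_hazard: float = 0.1
    assumed_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_fixed <= 1.0:
            raise ValueError("alpha_fixed must lie in [0, 1]")
        if not 0.0 <= self.adaptiveness <= 1.0:
            raise ValueError("adaptiveness must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.assumed_hazard <= 1.0:
            raise ValueError("assumed_hazard must lie in [0, 1]")
        if self.assumed_noise_sd <= 0:
            raise ValueError("assumed_noise_sd must be > 0")

    def to_dict(self) -> dict:
        return {
            "alpha_fixed": self.alpha_fixed,
            "adaptiveness": self.adaptiveness,
            "beta": self.beta,
            "assumed_hazard": self.assumed_hazard,
            "assumed_noise_sd": self.assumed_noise_sd,
            "seed": self.seed,
        }


@dataclass
class BeliefState:
    """Latent state of the (reduced Bayesian) observer.

    estimate : current point estimate E, task units.
    run_length : expected trials since the last inferred change (r >= 0).
    cp_prob : change-point probability omega from the last outcome.
    current_alpha : learning rate used on the last update, in [0, 1].
    """

    estimate: float
    run_length: float = INITIAL_RUN_LENGTH
    cp_prob: float = 0.0
    current_alpha: float = 0.0


@dataclass
class SessionRecord:
    """Full trial log of one simulated session.

    For the estimation task ``responses`` are grid predictions,
    ``outcomes`` the observed numbers, and ``estimates`` the scalar
    pre-trial internal estimate.  For the bandit task ``responses`` are
    chosen arm indices, ``outcomes`` the 0/1 rewards, and ``estimates``
    the (n_trials, n_arms) pre-trial value matrix.  ``realized_alphas``
    holds the learning rate actually used on each trial.
    """

    task_kind: str  # "estimation" | "bandit"
    environment: ChangePointSeries | BanditSchedule
    responses: np.ndarray
    outcomes: np.ndarray
    estimates: np.ndarray
    realized_alphas: np.ndarray
    agent: AgentConfig
    cp_probs: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.responses)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "response": self.responses,
                "outcome": self.outcomes,
                "realized_alpha": self.realized_alphas,
                "is_change": self.environment.is_change.astype(int),
            }
        )
        if self.estimates.ndim == 1:
            df["estimate"] = self.estimates
        else:
            for a in range(self.estimates.shape[1]):
                df[f"estimate_arm{a}"] = self.estimates[:, a]
        if self.cp_probs is not None:
            df["cp_prob"] = self.cp_probs
        return df

    def save(self, stem: Path | str) -> None:
        """Write ``<stem>.csv`` (trial log) + ``<stem>.json`` (agent/env)."""
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False, float_format="%.17g")
        sidecar = {
            "task_kind": self.task_kind,
            "agent": self.agent.to_dict(),
            "environment": self.environment.params(),
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def delta_update(estimate: float, outcome: float, learning_rate: float) -> float:
    """One delta-rule update: ``estimate + learning_rate * (outcome - estimate)``."""
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError(f"learning_rate must lie in [0, 1], got {learning_rate}")
    return estimate + learning_rate * (outcome - estimate)


def blend_learning_rate(
    alpha_fixed: float, alpha_bayes: float, adaptiveness: float
) -> float:
    """Convex blend ``(1 - lam) * alpha_fixed + lam * alpha_bayes``."""
    return (1.0 - adaptiveness) * alpha_fixed + adaptiveness * alpha_bayes


def _cp_quantities(
    estimate: float,
    run_length: float,
    outcome: float,
    assumed_hazard: float,
    assumed_noise_sd: float,
    outcome_range: tuple[float, float],
    bernoulli: bool = False,
) -> tuple[float, float]:
    """Change-point probability omega and Bayes learning rate alpha.

    Two-hypothesis Bayes rule: change (uniform density on the outcome
    range) vs. no change (Gaussian predictive with estimation
    uncertainty inflating the variance by 1/r).  With ``bernoulli`` the
    outcome is a 0/1 reward and the base predictive variance is the
    belief-dependent Bernoulli variance ``E*(1-E)``, floored at
    ``assumed_noise_sd**2``.
    """
    lo, hi = outcome_range
    h = assumed_hazard
    u = 1.0 / (hi - lo)
    if bernoulli:
        base_var = max(estimate * (1.0 - estimate), assumed_noise_sd**2)
    else:
        base_var = assumed_noise_sd**2
    var = base_var * (1.0 + 1.0 / run_length)
    delta = outcome - estimate
    g = np.exp(-0.5 * delta * delta / var) / np.sqrt(2.0 * np.pi * var)
    num = h * u
    denom = num + (1.0 - h) * g
    omega = num / denom if denom > 0 else 1.0
    alpha = omega + (1.0 - omega) / (run_length + 1.0)
    return float(omega), float(alpha)


def reduced_bayes_step(
    belief: BeliefState,
    outcome: float,
    assumed_hazard: float,
    assumed_noise_sd: float,
    outcome_range: tuple[float, float],
) -> BeliefState:
    """One update of the reduced Bayesian change-point observer.

    Returns the new belief with the estimate moved by the adaptive
    learning rate and the expected run length propagated as
    ``r' = (r + 1) * (1 - omega) + omega`` (a fully detected change
    resets r toward 1).
    """
    if assumed_noise_sd <= 0:
        raise ValueError("assumed_noise_sd must be > 0")
    omega, alpha = _cp_quantities(
        belief.estimate,
        belief.run_length,
        outcome,
        assumed_hazard,
        assumed_noise_sd,
        outcome_range,
    )
    new_estimate = belief.estimate + alpha * (outcome - belief.estimate)
    new_r = (belief.run_length + 1.0) * (1.0 - omega) + omega
    return BeliefState(
        estimate=new_estimate, run_length=new_r, cp_prob=omega, current_alpha=alpha
    )


def softmax_probs(values: np.ndarray, beta: float) -> np.ndarray:
    """Soft-max choice probabilities ``p_i ∝ exp(beta * v_i)``.

    Computed with max-subtraction so large ``beta * v`` never overflows.
    ``beta = 0`` yields the uniform distribution.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * values
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def log_softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Row-wise log soft-max of precomputed scores (``beta * values``)."""
    scores = np.asarray(scores, dtype=float)
    m = scores.max(axis=axis, keepdims=True)
    z = scores - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    return z - lse


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))


def prediction_grid(
    outcome_range: tuple[float, float], step: float = 1.0
) -> np.ndarray:
    """Integer response grid for the estimation task (inclusive of both ends)."""
    lo, hi = outcome_range
    return np.arange(lo, hi + 0.5 * step, step)


def simulate_estimation_session(
    series: ChangePointSeries,
    agent: AgentConfig,
    grid_step: float = 1.0,
) -> SessionRecord:
    """Simulate one estimation-task session.

    Per trial the agent emits a prediction by soft-max over the response
    grid (quadratic utility around its current estimate), observes the
    outcome, computes the reduced-Bayes learning rate, blends it with
    the fixed rate by ``adaptiveness``, and updates its estimate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(agent.seed))
    grid = prediction_grid(series.outcome_range, grid_step)
    n = series.n_trials
    lo, hi = series.outcome_range
    inv_2s2 = 1.0 / (2.0 * agent.assumed_noise_sd**2)

    estimate = 0.5 * (lo + hi)
    run_length = INITIAL_RUN_LENGTH
    lam = agent.adaptiveness

    responses = np.empty(n)
    estimates = np.empty(n)
    alphas = np.empty(n)
    cp_probs = np.empty(n)

    for t in range(n):
        estimates[t] = estimate
        utilities = -((grid - estimate) ** 2) * inv_2s2
        probs = softmax_probs(utilities, agent.beta)
        responses[t] = grid[_sample_categorical(rng, probs)]

        outcome = series.outcomes[t]
        omega, alpha_bayes = _cp_quantities(
            estimate,
            run_length,
            outcome,
            agent.assumed_hazard,
            agent.assumed_noise_sd,
            series.outcome_range,
        )
        alpha_t = blend_learning_rate(agent.alpha_fixed, alpha_bayes, lam)
        estimate = estimate + alpha_t * (outcome - estimate)
        run_length = (run_length + 1.0) * (1.0 - omega) + omega
        alphas[t] = alpha_t
        cp_probs[t] = omega

    return SessionRecord(
        task_kind="estimation",
        environment=series,
        responses=responses,
        outcomes=series.outcomes.copy(),
        estimates=estimates,
        realized_alphas=alphas,
        agent=replace(agent),
        cp_probs=cp_probs,
    )


def simulate_bandit_session(
    schedule: BanditSchedule,
    agent: AgentConfig,
    q_init: float = BANDIT_Q_INIT,
) -> SessionRecord:
    """Simulate one four-choice bandit session.

    Choices are soft-max over per-arm value estimates; only the chosen
    arm's value is updated, with the blended learning rate.  The
    change-point machinery is driven by the chosen arm's Bernoulli
    prediction error, with a uniform alternative density of 1 on [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence(agent.seed))
    n, n_arms = schedule.n_trials, schedule.n_arms
    q = np.full(n_arms, q_init)
    run_length = INITIAL_RUN_LENGTH
    lam = agent.adaptiveness

    choices = np.empty(n, dtype=int)
    rewards = np.empty(n)
    estimates = np.empty((n, n_arms))
    alphas = np.empty(n)
    cp_probs = np.empty(n)

    for t in range(n):
        estimates[t] = q
        probs = softmax_probs(q, agent.beta)
        a = _sample_categorical(rng, probs)
        choices[t] = a
        reward = float(rng.random() < schedule.reward_probs[t, a])
        rewards[t] = reward

        omega, alpha_bayes = _cp_quantities(
            q[a],
            run_length,
            reward,
            agent.assumed_hazard,
            agent.assumed_noise_sd,
            (0.0, 1.0),
            bernoulli=True,
        )
        alpha_t = blend_learning_rate(agent.alpha_fixed, alpha_bayes, lam)
        q[a] = q[a] + alpha_t * (reward - q[a])
        run_length = (run_length + 1.0) * (1.0 - omega) + omega
        alphas[t] = alpha_t
        cp_probs[t] = omega

    return SessionRecord(
        task_kind="bandit",
        environment=schedule,
        responses=choices,
        outcomes=rewards,
        estimates=estimates,
        realized_alphas=alphas,
        agent=replace(agent),
        cp_probs=cp_probs,
    )
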