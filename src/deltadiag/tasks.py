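"""Synthetic task environments with unsignaled change-points.

Two task families are generated here:

* an **estimation task** in which each outcome is drawn from a Gaussian
  whose latent mean occasionally resets ("change-point") to a fresh
  uniform draw on the outcome range, and
* a **four-alternative bandit task** in which each arm pays a Bernoulli
  reward whose probability is reassigned (a fresh permutation of a fixed
  probability set) at unsignaled change-points.

Both generators are fully reproducible from an integer seed and keep
the change-point stream independent of the outcome-noise stream, so the
same change-point layout can be replayed under different noise draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChangePointSeries",
    "BanditSchedule",
    "generate_changepoint_series",
    "generate_bandit_schedule",
]

#: Estimation-task defaults: outcome range, outcome noise SD, per-trial hazard.
DEFAULT_OUTCOME_RANGE: tuple[float, float] = (0.0, 300.0)
DEFAULT_NOISE_SD: float = 20.0
DEFAULT_HAZARD: float = 0.1

#: Bandit defaults: one clearly best arm; change-points rare relative to
#: the learning timescale.
DEFAULT_PROB_SET: tuple[float, ...] = (0.8, 0.4, 0.2, 0.1)
DEFAULT_BANDIT_HAZARD: float = 0.04
DEFAULT_N_TRIALS: int = 800


@dataclass
class ChangePointSeries:
    """Outcome sequence for the estimation task.

    Attributes
    ----------
    outcomes : per-trial observed outcome (task units).
    means : per-trial latent generative mean.
    is_change : per-trial change-point indicator; trial 0 counts as a
        change-point by convention (the first mean is a fresh draw).
    hazard : per-trial probability of a mean reset.
    noise_sd : SD of outcome noise around the latent mean.
    outcome_range : closed interval ``[lo, hi]`` containing all outcomes.
    """

    outcomes: np.ndarray
    means: np.ndarray
    is_change: np.ndarray
    hazard: float
    noise_sd: float
    outcome_range: tuple[float, float]
    n_trials: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """One row per trial: index, latent mean, outcome, change flag."""
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "mean": self.means,
                "outcome": self.outcomes,
                "is_change": self.is_change.astype(int),
            }
        )

    def params(self) -> dict:
        return {
            "kind": "estimation",
            "n_trials": self.n_trials,
            "hazard": self.hazard,
            "noise_sd": self.noise_sd,
            "outcome_range": list(self.outcome_range),
            "seed": self.seed,
        }

    def save(self, stem: Path | str) -> None:
        """Write ``<stem>.csv`` (trials) and ``<stem>.json`` (parameters)."""
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False, float_format="%.17g")
        stem.with_suffix(".json").write_text(json.dumps(self.params(), indent=2))


@dataclass
class BanditSchedule:
    """Per-trial per-arm reward probabilities for the four-choice task.

    Each row of ``reward_probs`` is a permutation of ``prob_set``; the
    permutation is redrawn (and forced to differ from its predecessor)
    at every change-point, so each flagged change-point is a real
    contingency change.
    """

    reward_probs: np.ndarray  # (n_trials, n_arms)
    n_arms: int
    is_change: np.ndarray
    hazard: float
    prob_set: tuple[float, ...]
    n_trials: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.reward_probs,
            columns=[f"p_arm{a}" for a in range(self.n_arms)],
        )
        df.insert(0, "trial", np.arange(self.n_trials))
        df["is_change"] = self.is_change.astype(int)
        return df

    def params(self) -> dict:
        return {
            "kind": "bandit",
            "n_trials": self.n_trials,
            "n_arms": self.n_arms,
            "hazard": self.hazard,
            "prob_set": list(self.prob_set),
            "seed": self.seed,
        }

    def save(self, stem: Path | str) -> None:
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False, float_format="%.17g")
        stem.with_suffix(".json").write_text(json.dumps(self.params(), indent=2))


def _validate_hazard(hazard: float) -> None:
    if not 0.0 <= hazard <= 1.0:
        raise ValueError(f"hazard must lie in [0, 1], got {hazard}")


def generate_changepoint_series(
    n_trials: int = DEFAULT_N_TRIALS,
    hazard: float = DEFAULT_HAZARD,
    noise_sd: float = DEFAULT_NOISE_SD,
    outcome_range: tuple[float, float] = DEFAULT_OUTCOME_RANGE,
    seed: int = 0,
) -> ChangePointSeries:
    """Generate a Gaussian outcome series whose mean resets at random times.

    On each trial after the first, with probability ``hazard`` the latent
    mean is redrawn uniformly on ``outcome_range``; the outcome is then
    Normal(mean, noise_sd**2), rejection-sampled into the outcome range
    (resampled, not clipped, so the Gaussian likelihood stays honest near
    the boundaries).

    Change-point draws, mean draws and outcome noise use independent
    seeded substreams, all derived from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    _validate_hazard(hazard)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    lo, hi = float(outcome_range[0]), float(outcome_range[1])
    if not lo < hi:
        raise ValueError(f"outcome_range must satisfy lo < hi, got ({lo}, {hi})")

    ss = np.random.SeedSequence(seed)
    rng_change, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    is_change = np.empty(n_trials, dtype=bool)
    is_change[0] = True  # fresh draw convention
    if n_trials > 1:
        is_change[1:] = rng_change.random(n_trials - 1) < hazard

    means = np.empty(n_trials)
    change_idx = np.flatnonzero(is_change)
    fresh = rng_change.uniform(lo, hi, size=change_idx.size)
    # piecewise-constant fill between change-points
    seg = np.cumsum(is_change) - 1
    means[:] = fresh[seg]

    outcomes = means + rng_noise.normal(0.0, noise_sd, size=n_trials)
    out_of_range = (outcomes < lo) | (outcomes > hi)
    while np.any(out_of_range):
        k = int(out_of_range.sum())
        outcomes[out_of_range] = means[out_of_range] + rng_noise.normal(
            0.0, noise_sd, size=k
        )
        out_of_range = (outcomes < lo) | (outcomes > hi)

    return ChangePointSeries(
        outcomes=outcomes,
        means=means,
        is_change=is_change,
        hazard=hazard,
        noise_sd=noise_sd,
        outcome_range=(lo, hi),
        n_trials=n_trials,
        seed=seed,
    )


def generate_bandit_schedule(
    n_trials: int = DEFAULT_N_TRIALS,
    n_arms: int = 4,
    hazard: float = DEFAULT_BANDIT_HAZARD,
    prob_set: tuple[float, ...] = DEFAULT_PROB_SET,
    seed: int = 0,
) -> BanditSchedule:
    """Generate a bandit reward schedule with change-point reassignments.

    At each change-point the arm→probability assignment is redrawn as a
    uniformly random permutation of ``prob_set`` that differs from the
    previous assignment; between change-points the assignment is constant.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    _validate_hazard(hazard)
    if len(prob_set) != n_arms:
        raise ValueError(
            f"prob_set length ({len(prob_set)}) must equal n_arms ({n_arms})"
        )
    probs = np.asarray(prob_set, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("prob_set entries must lie in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    is_change = np.empty(n_trials, dtype=bool)
    is_change[0] = True
    if n_trials > 1:
        is_change[1:] = rng.random(n_trials - 1) < hazard

    # a new permutation can only be forced to differ if the set is not uniform
    can_differ = np.unique(probs).size > 1
    reward_probs = np.empty((n_trials, n_arms))
    current = probs[rng.permutation(n_arms)]
    reward_probs[0] = current
    for t in range(1, n_trials):
        if is_change[t]:
            new = probs[rng.permutation(n_arms)]
            while can_differ and np.array_equal(new, current):
                new = probs[rng.permutation(n_arms)]
            current = new
        reward_probs[t] = current

    return BanditSchedule(
        reward_probs=reward_probs,
        n_arms=n_arms,
        is_change=is_change,
        hazard=hazard,
        prob_set=tuple(float(p) for p in prob_set),
        n_trials=n_trials,
        seed=seed,
    )
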