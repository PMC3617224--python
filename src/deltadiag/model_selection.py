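"""Information-criterion model comparison against a random-choice null.

A fitted learning model is compared with a zero-parameter null model in
which every response option is equally likely on every trial (1/4 per
arm in the bandit task; 1/G per grid point in the estimation task).
AIC and BIC use the standard penalties 2k and k ln n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import SessionRecord, prediction_grid
from .fitting import FitResult

__all__ = ["null_model_loglik", "information_criteria", "comparison_table"]


def null_model_loglik(session: SessionRecord) -> float:
    """Log-likelihood of uniformly random responding over the session.

    Bandit: ``n_trials * ln(1/n_arms)``.  Estimation:
    ``n_trials * ln(1/G)`` for a response grid of size G.
    """
    n = session.n_trials
    if session.task_kind == "bandit":
        return float(n * np.log(1.0 / session.environment.n_arms))
    g = prediction_grid(session.environment.outcome_range).size
    return float(n * np.log(1.0 / g))


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 loglik; BIC = k ln(n) - 2 loglik."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * np.log(n) - 2.0 * loglik
    return float(aic), float(bic)


def comparison_table(
    fits: dict[str, FitResult],
    null_loglik: float,
    n_obs: int,
    label: dict | None = None,
) -> pd.DataFrame:
    """Tidy comparison of fitted models against the random-choice null.

    One row per model (including the null), with k, log-likelihood, AIC,
    BIC and the BIC advantage over the null (positive = preferred).
    Extra ``label`` columns (e.g. the agent's adaptiveness) are prepended
    to every row.
    """
    null_aic, null_bic = information_criteria(null_loglik, 0, n_obs)
    rows = [
        {
            "model": "null",
            "k": 0,
            "loglik": null_loglik,
            "aic": null_aic,
            "bic": null_bic,
            "delta_bic_vs_null": 0.0,
        }
    ]
    for name, fit in fits.items():
        rows.append(
            {
                "model": name,
                "k": len(fit.param_names),
                "loglik": fit.loglik,
                "aic": fit.aic,
                "bic": fit.bic,
                "delta_bic_vs_null": null_bic - fit.bic,
            }
        )
    df = pd.DataFrame(rows)
    if label:
        for i, (key, val) in enumerate(label.items()):
            df.insert(i, key, val)
    return df
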