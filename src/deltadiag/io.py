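"""Round-trip serialization of simulated sessions.

A session is stored as ``<stem>.csv`` (one row per trial) plus
``<stem>.json`` (agent parameters and environment generator parameters).
Environments are regenerated exactly from their recorded seed, so the
pair reconstructs the full :class:`~deltadiag.agents.SessionRecord`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AgentConfig, SessionRecord
from .tasks import generate_bandit_schedule, generate_changepoint_series

__all__ = ["load_session"]


def load_session(stem: Path | str) -> SessionRecord:
    """Load a session written by :meth:`SessionRecord.save`.

    Raises ``FileNotFoundError`` if either file of the pair is missing
    and ``ValueError`` if the stored trial log is inconsistent with the
    regenerated environment.
    """
    stem = Path(stem)
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")

    env_p = meta["environment"]
    if env_p["kind"] == "estimation":
        env = generate_changepoint_series(
            env_p["n_trials"],
            env_p["hazard"],
            env_p["noise_sd"],
            tuple(env_p["outcome_range"]),
            seed=env_p["seed"],
        )
    else:
        env = generate_bandit_schedule(
            env_p["n_trials"],
            env_p["n_arms"],
            env_p["hazard"],
            tuple(env_p["prob_set"]),
            seed=env_p["seed"],
        )
    if len(df) != env_p["n_trials"]:
        raise ValueError(f"{csv_path}: trial count does not match environment")
    if not np.array_equal(df["is_change"].to_numpy(dtype=bool), env.is_change):
        raise ValueError(f"{csv_path}: change flags do not match regenerated environment")

    task_kind = meta["task_kind"]
    if task_kind == "bandit":
        est_cols = [c for c in df.columns if c.startswith("estimate_arm")]
        estimates = df[est_cols].to_numpy()
        responses = df["response"].to_numpy(dtype=int)
    else:
        estimates = df["estimate"].to_numpy()
        responses = df["response"].to_numpy(dtype=float)

    return SessionRecord(
        task_kind=task_kind,
        environment=env,
        responses=responses,
        outcomes=df["outcome"].to_numpy(dtype=float),
        estimates=estimates,
        realized_alphas=df["realized_alpha"].to_numpy(dtype=float),
        agent=AgentConfig(**meta["agent"]),
        cp_probs=df["cp_prob"].to_numpy(dtype=float) if "cp_prob" in df else None,
    )
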