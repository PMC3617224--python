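"""End-to-end experiments: the parameter-bias sweep and the misfit
diagnostics, for both tasks.

``run_bias_experiment`` sweeps agents over an adaptiveness grid at two
exploration levels per task, simulates sessions, logs the realized
learning-rate distribution, and fits the fixed-rate, adaptive (Bayes)
and null models — the analogue of plotting actual vs. model-inferred
learning rates and inverse temperatures against adaptiveness.

``run_diagnostics_experiment`` fits the fixed-rate model across the
adaptiveness grid and computes change-point-aligned likelihood profiles
and exclusion refits (windows 0..10) for both tasks.

A single master seed deterministically derives every environment and
agent seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import (
    AgentConfig,
    SessionRecord,
    simulate_bandit_session,
    simulate_estimation_session,
)
from .diagnostics import (
    aligned_loglik_profile,
    exclusion_refit,
    learning_rate_summary,
)
from .fitting import fit_mle, trial_logliks_fixed
from .model_selection import null_model_loglik
from .tasks import generate_bandit_schedule, generate_changepoint_series

__all__ = ["ExperimentConfig", "run_bias_experiment", "run_diagnostics_experiment"]

log = logging.getLogger("deltadiag")


@dataclass
class ExperimentConfig:
    """Study conditions for both experiments.

    The defaults are the package's reference conditions: six sessions of
    800 trials per condition, an adaptiveness grid spanning the fixed
    delta rule to the reduced Bayesian observer, and two generative
    exploration levels per task.
    """

    # shared
    lam_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    alpha_fixed: float = 0.3
    n_sessions: int = 6
    n_trials: int = 800
    tasks: tuple[str, ...] = ("estimation", "bandit")
    seed: int = 0
    output_dir: str | None = None
    n_restarts: int = 10

    # estimation task
    est_hazard: float = 0.1
    est_noise_sd: float = 20.0
    est_range: tuple[float, float] = (0.0, 300.0)
    est_betas: tuple[float, ...] = (0.5, 4.0)

    # bandit task
    bandit_hazard: float = 0.04
    n_arms: int = 4
    prob_set: tuple[float, ...] = (0.8, 0.4, 0.2, 0.1)
    bandit_noise_sd: float = 0.2  # floor on the observer's assumed reward SD
    bandit_betas: tuple[float, ...] = (5.0, 10.0)

    # diagnostics experiment: one exploration level per task, a coarser
    # adaptiveness grid, and warm-started refits (which need fewer cold
    # restarts than a cold fit)
    diag_lam_grid: tuple[float, ...] = (0.0, 0.5, 1.0)
    diag_est_beta: float = 2.0
    diag_bandit_beta: float = 5.0
    max_offset: int = 10
    windows: tuple[int, ...] = tuple(range(11))
    diag_n_restarts: int = 4

    def __post_init__(self) -> None:
        if any(not 0.0 <= l <= 1.0 for l in self.lam_grid):
            raise ValueError("lam_grid values must lie in [0, 1]")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        unknown = set(self.tasks) - {"estimation", "bandit"}
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = {}
        for k, v in d.items():
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key: {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def derive_seed(master: int, *tags) -> int:
    """Deterministic child seed (< 2**31) from a master seed and tags.

    Strings are hashed with CRC32 (stable across processes, unlike
    Python's randomized ``hash``); numbers are used at fixed precision.
    """
    key = tuple(
        zlib.crc32(t.encode()) if isinstance(t, str) else int(round(t * 10000))
        for t in tags
    )
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def _manifest_config(config: ExperimentConfig) -> dict:
    """Config as recorded in manifests: the output path is location
    metadata, not a study condition, and is omitted so reruns into
    different directories produce identical manifests."""
    d = config.to_dict()
    d.pop("output_dir", None)
    return d


def _environments(config: ExperimentConfig, task: str) -> list:
    """One environment set per task, shared across agent conditions
    (common random numbers across the adaptiveness sweep)."""
    envs = []
    for i in range(config.n_sessions):
        s = derive_seed(config.seed, "env", task, i)
        if task == "estimation":
            envs.append(
                generate_changepoint_series(
                    config.n_trials,
                    config.est_hazard,
                    config.est_noise_sd,
                    config.est_range,
                    seed=s,
                )
            )
        else:
            envs.append(
                generate_bandit_schedule(
                    config.n_trials,
                    config.n_arms,
                    config.bandit_hazard,
                    config.prob_set,
                    seed=s,
                )
            )
    return envs


def _agent(config: ExperimentConfig, task: str, lam: float, beta: float, i: int) -> AgentConfig:
    if task == "estimation":
        return AgentConfig(
            alpha_fixed=config.alpha_fixed,
            adaptiveness=lam,
            beta=beta,
            assumed_hazard=config.est_hazard,
            assumed_noise_sd=config.est_noise_sd,
            seed=derive_seed(config.seed, "agent", task, lam, beta, i),
        )
    return AgentConfig(
        alpha_fixed=config.alpha_fixed,
        adaptiveness=lam,
        beta=beta,
        assumed_hazard=config.bandit_hazard,
        assumed_noise_sd=config.bandit_noise_sd,
        seed=derive_seed(config.seed, "agent", task, lam, beta, i),
    )


def simulate_condition(
    config: ExperimentConfig, task: str, lam: float, beta: float, envs: list | None = None
) -> list[SessionRecord]:
    """Simulate ``n_sessions`` sessions of one (task, lam, beta) condition."""
    envs = envs if envs is not None else _environments(config, task)
    sim = simulate_estimation_session if task == "estimation" else simulate_bandit_session
    return [sim(env, _agent(config, task, lam, beta, i)) for i, env in enumerate(envs)]


def _save_sessions(
    sessions: list[SessionRecord], outdir: Path, task: str, lam: float, beta: float
) -> list[str]:
    sdir = outdir / "sessions"
    sdir.mkdir(parents=True, exist_ok=True)
    stems = []
    for i, s in enumerate(sessions):
        stem = sdir / f"{task}_beta{beta:g}_lam{lam:g}_session{i}"
        s.save(stem)
        stems.append(stem.name)
    return stems


def run_bias_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep adaptiveness and fit all models: the parameter-bias table.

    Returns one row per (task, generative beta, adaptiveness, model)
    with the realized learning-rate summary, fitted parameters with
    standard errors, and information criteria against the null model.
    Sessions and tables are written under ``config.output_dir`` if set.
    """
    rows = []
    outdir = Path(config.output_dir) if config.output_dir else None
    manifest: dict = {"experiment": "bias", "config": _manifest_config(config), "conditions": []}
    for task in config.tasks:
        envs = _environments(config, task)
        betas = config.est_betas if task == "estimation" else config.bandit_betas
        for beta in betas:
            for lam in config.lam_grid:
                t0 = time.perf_counter()
                sessions = simulate_condition(config, task, lam, beta, envs)
                alphas = np.concatenate([s.realized_alphas for s in sessions])
                med, (q25, q75) = learning_rate_summary(alphas)
                seed_fit = derive_seed(config.seed, "fit", task, lam, beta)
                fits = {
                    "fixed_lr": fit_mle(
                        "fixed_lr", sessions, n_restarts=config.n_restarts, seed=seed_fit
                    ),
                    "bayes_lr": fit_mle(
                        "bayes_lr", sessions, n_restarts=config.n_restarts, seed=seed_fit
                    ),
                }
                null_ll = float(sum(null_model_loglik(s) for s in sessions))
                n_obs = sum(s.n_trials for s in sessions)
                null_bic = -2.0 * null_ll
                for name, fit in fits.items():
                    rows.append(
                        {
                            "task": task,
                            "beta_gen": beta,
                            "alpha_gen": config.alpha_fixed,
                            "lam": lam,
                            "model": name,
                            "median_realized_alpha": med,
                            "iqr_lo": q25,
                            "iqr_hi": q75,
                            "alpha_hat": fit.params.get("alpha", np.nan),
                            "beta_hat": fit.params.get("beta", np.nan),
                            "alpha_se": fit.stderr.get("alpha", np.nan),
                            "beta_se": fit.stderr.get("beta", np.nan),
                            "loglik": fit.loglik,
                            "aic": fit.aic,
                            "bic": fit.bic,
                            "null_loglik": null_ll,
                            "delta_bic_vs_null": null_bic - fit.bic,
                            "converged": fit.converged,
                            "n_obs": fit.n_obs,
                        }
                    )
                if outdir:
                    stems = _save_sessions(sessions, outdir, task, lam, beta)
                    manifest["conditions"].append(
                        {"task": task, "beta": beta, "lam": lam, "sessions": stems}
                    )
                log.info(
                    "bias %s beta=%g lam=%g done in %.1fs",
                    task,
                    beta,
                    lam,
                    time.perf_counter() - t0,
                )
    df = pd.DataFrame(rows)
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "bias_table.csv", index=False)
        (outdir / "bias_manifest.json").write_text(json.dumps(manifest, indent=2))
    return df


def run_diagnostics_experiment(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned likelihood profiles and exclusion refits for both tasks.

    Returns ``(profiles, exclusion)`` data frames.  ``profiles`` has one
    row per (task, adaptiveness, offset), the terminal steady-state bin
    included as offset -1; ``exclusion`` one row per (task,
    adaptiveness, window) with the refit parameters.
    """
    prof_rows, excl_rows = [], []
    outdir = Path(config.output_dir) if config.output_dir else None
    manifest: dict = {
        "experiment": "diagnostics",
        "config": _manifest_config(config),
        "conditions": [],
    }
    for task in config.tasks:
        envs = _environments(config, task)
        beta = config.diag_est_beta if task == "estimation" else config.diag_bandit_beta
        for lam in config.diag_lam_grid:
            t0 = time.perf_counter()
            sessions = simulate_condition(config, task, lam, beta, envs)
            seed_fit = derive_seed(config.seed, "diagfit", task, lam, beta)
            fit = fit_mle(
                "fixed_lr", sessions, n_restarts=config.n_restarts, seed=seed_fit
            )
            lls = [
                trial_logliks_fixed(fit.params["alpha"], fit.params["beta"], s)
                for s in sessions
            ]
            prof = aligned_loglik_profile(
                lls,
                [s.environment.is_change for s in sessions],
                max_offset=config.max_offset,
            )
            for o, m, se, n in zip(
                prof.offsets, prof.mean_loglik, prof.se_loglik, prof.n_contributing
            ):
                prof_rows.append(
                    {
                        "task": task,
                        "beta_gen": beta,
                        "lam": lam,
                        "offset": int(o),
                        "mean_loglik": m,
                        "se_loglik": se,
                        "n_contributing": int(n),
                    }
                )
            prof_rows.append(
                {
                    "task": task,
                    "beta_gen": beta,
                    "lam": lam,
                    "offset": -1,  # terminal steady-state bin
                    "mean_loglik": prof.terminal_mean,
                    "se_loglik": prof.terminal_se,
                    "n_contributing": prof.terminal_n,
                }
            )
            curve = exclusion_refit(
                sessions,
                "fixed_lr",
                windows=config.windows,
                n_restarts=config.diag_n_restarts,
                seed=derive_seed(config.seed, "excl", task, lam, beta),
            )
            med, _ = learning_rate_summary(
                np.concatenate([s.realized_alphas for s in sessions])
            )
            for w, a, b, f in zip(
                curve.window, curve.alpha_hat, curve.beta_hat, curve.fits
            ):
                excl_rows.append(
                    {
                        "task": task,
                        "beta_gen": beta,
                        "lam": lam,
                        "window": int(w),
                        "alpha_hat": a,
                        "beta_hat": b,
                        "median_realized_alpha": med,
                        "converged": f.converged,
                        "n_obs": f.n_obs,
                    }
                )
            if outdir:
                stems = _save_sessions(sessions, outdir, task, lam, beta)
                manifest["conditions"].append(
                    {"task": task, "beta": beta, "lam": lam, "sessions": stems}
                )
            log.info(
                "diagnostics %s lam=%g done in %.1fs",
                task,
                lam,
                time.perf_counter() - t0,
            )
    profiles = pd.DataFrame(prof_rows)
    exclusion = pd.DataFrame(excl_rows)
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        profiles.to_csv(outdir / "aligned_profiles.csv", index=False)
        exclusion.to_csv(outdir / "exclusion_fits.csv", index=False)
        (outdir / "diagnostics_manifest.json").write_text(json.dumps(manifest, indent=2))
    return profiles, exclusion
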