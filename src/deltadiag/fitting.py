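"""Maximum-likelihood fitting of learning models to simulated sessions.

Three candidate models are fit to a session's recorded responses:

* ``fixed_lr`` — delta rule with a fixed learning rate; free parameters
  ``alpha`` (learning rate) and ``beta`` (inverse temperature);
* ``bayes_lr`` — reduced Bayesian observer (maximally adaptive learning
  rate); the only free parameter is ``beta``;
* ``null`` — random choice; no free parameters.

Fitting replays the model's internal estimates over the *recorded*
outcomes and scores the *recorded* responses under the soft-max
response model, so the likelihood factorizes over trials.  Parameters
are optimized in unconstrained coordinates (logit for ``alpha``, log
for ``beta``) by quasi-random multistart Nelder-Mead with a
derivative-based polish, and standard errors come from the inverse
numerical Hessian at the optimum, delta-method mapped back to the
natural scale.

Excluded trials (``include_mask`` False) contribute nothing to the
summed log-likelihood but the model still updates through them, so the
replayed belief trajectory is unaffected by exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.signal import lfilter
from scipy.special import expit, logit

from .agents import (
    BANDIT_Q_INIT,
    SessionRecord,
    log_softmax,
    prediction_grid,
    _cp_quantities,
)

__all__ = [
    "FitResult",
    "trial_logliks_fixed",
    "trial_logliks_bayes",
    "fit_mle",
    "wald_ci",
    "MODEL_PARAM_NAMES",
]

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "fixed_lr": ("alpha", "beta"),
    "bayes_lr": ("beta",),
    "null": (),
}

_GRID_STEP = 1.0


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit.

    ``params``/``stderr`` are keyed by parameter name; ``covariance`` is
    on the natural (alpha, beta) scale in the order of ``param_names``.
    ``aic``/``bic`` use the number of *included* trials as ``n_obs``.
    """

    model_id: str
    params: dict[str, float]
    loglik: float
    n_obs: int
    aic: float
    bic: float
    stderr: dict[str, float]
    covariance: np.ndarray
    converged: bool
    n_restarts: int
    exclusion_window: int = 0
    param_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "stderr": self.stderr,
            "covariance": np.asarray(self.covariance).tolist(),
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "exclusion_window": self.exclusion_window,
        }

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def wald_ci(fit: FitResult, name: str, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval ``estimate ± z * stderr`` on the natural scale."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    est, se = fit.params[name], fit.stderr[name]
    return est - z * se, est + z * se


# ---------------------------------------------------------------------------
# belief-trajectory replays


def _initial_estimate(session: SessionRecord) -> float:
    lo, hi = session.environment.outcome_range
    return 0.5 * (lo + hi)


def _replay_fixed_estimation(
    outcomes: np.ndarray, alpha: float, e0: float
) -> np.ndarray:
    """Pre-trial estimate trajectory of a fixed-alpha delta rule.

    The recursion E[t+1] = (1-a) E[t] + a X[t] is a first-order linear
    filter, evaluated in C by ``scipy.signal.lfilter``.
    """
    n = len(outcomes)
    est = np.empty(n)
    est[0] = e0
    if n > 1:
        y, _ = lfilter(
            [alpha], [1.0, -(1.0 - alpha)], outcomes[:-1], zi=[(1.0 - alpha) * e0]
        )
        est[1:] = y
    return est


def _replay_fixed_bandit(
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha: float,
    n_arms: int,
    q0: float = BANDIT_Q_INIT,
) -> np.ndarray:
    """Pre-trial per-arm value matrix under a fixed-alpha delta rule.

    Only the chosen arm updates, so each arm's value trajectory is a
    delta rule over the subsequence of trials on which it was chosen;
    values are forward-filled in between.
    """
    n = len(choices)
    q = np.empty((n, n_arms))
    trials = np.arange(n)
    for a in range(n_arms):
        idx = np.flatnonzero(choices == a)
        if idx.size == 0:
            q[:, a] = q0
            continue
        y, _ = lfilter(
            [alpha], [1.0, -(1.0 - alpha)], rewards[idx], zi=[(1.0 - alpha) * q0]
        )
        # number of updates of arm a strictly before each trial
        cnt = np.searchsorted(idx, trials, side="left")
        q[:, a] = np.concatenate(([q0], y))[cnt]
    return q


def _replay_bayes_estimation(
    outcomes: np.ndarray,
    assumed_hazard: float,
    assumed_noise_sd: float,
    outcome_range: tuple[float, float],
    e0: float,
) -> np.ndarray:
    """Pre-trial estimate trajectory of the reduced Bayesian observer."""
    n = len(outcomes)
    est = np.empty(n)
    e, r = e0, 1.0
    for t in range(n):
        est[t] = e
        omega, alpha = _cp_quantities(
            e, r, outcomes[t], assumed_hazard, assumed_noise_sd, outcome_range
        )
        e = e + alpha * (outcomes[t] - e)
        r = (r + 1.0) * (1.0 - omega) + omega
    return est


def _replay_bayes_bandit(
    choices: np.ndarray,
    rewards: np.ndarray,
    n_arms: int,
    assumed_hazard: float,
    assumed_noise_sd: float,
    q0: float = BANDIT_Q_INIT,
) -> np.ndarray:
    """Pre-trial value matrix of the reduced Bayesian observer (bandit)."""
    n = len(choices)
    qmat = np.empty((n, n_arms))
    q = np.full(n_arms, q0)
    r = 1.0
    for t in range(n):
        qmat[t] = q
        a = choices[t]
        omega, alpha = _cp_quantities(
            q[a], r, rewards[t], assumed_hazard, assumed_noise_sd, (0.0, 1.0),
            bernoulli=True,
        )
        q[a] = q[a] + alpha * (rewards[t] - q[a])
        r = (r + 1.0) * (1.0 - omega) + omega
    return qmat


# ---------------------------------------------------------------------------
# per-trial log-likelihoods


def _estimation_logliks(
    estimates: np.ndarray,
    responses: np.ndarray,
    grid: np.ndarray,
    beta: float,
    inv_2s2: float,
) -> np.ndarray:
    """Log soft-max probability of each recorded grid prediction.

    The utility of predicting p with estimate E is -(p - E)^2/(2 s^2);
    the row maximum sits at the grid point nearest E, which gives an
    exact max-subtraction without scanning the utility matrix twice.
    """
    lo, hi, step = grid[0], grid[-1], _GRID_STEP
    d = grid[None, :] - estimates[:, None]
    scores = -beta * d * d * inv_2s2
    nearest = np.clip(np.round((estimates - lo) / step) * step + lo, lo, hi)
    m = -beta * (nearest - estimates) ** 2 * inv_2s2
    lse = m + np.log(np.exp(scores - m[:, None]).sum(axis=1))
    u_resp = -beta * (responses - estimates) ** 2 * inv_2s2
    return u_resp - lse


def _bandit_logliks(qmat: np.ndarray, choices: np.ndarray, beta: float) -> np.ndarray:
    lp = log_softmax(beta * qmat, axis=1)
    return lp[np.arange(len(choices)), choices]


def _check_session(session: SessionRecord) -> None:
    if session.task_kind == "bandit":
        n_arms = session.environment.n_arms
        ch = np.asarray(session.responses)
        if ch.min() < 0 or ch.max() >= n_arms:
            raise ValueError("bandit responses outside the valid arm set")
    else:
        lo, hi = session.environment.outcome_range
        r = np.asarray(session.responses, dtype=float)
        if r.min() < lo or r.max() > hi:
            raise ValueError("estimation responses outside the prediction grid")


def trial_logliks_fixed(
    alpha: float,
    beta: float,
    session: SessionRecord,
    assumed_noise_sd: float | None = None,
) -> np.ndarray:
    """Per-trial log-likelihood of the fixed learning-rate model.

    Replays a fixed-``alpha`` delta rule over the session's observed
    outcomes from the same initial estimate used generatively, then
    scores each recorded response under the soft-max response model.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    _check_session(session)
    if session.task_kind == "estimation":
        sd = assumed_noise_sd or session.agent.assumed_noise_sd
        grid = prediction_grid(session.environment.outcome_range, _GRID_STEP)
        est = _replay_fixed_estimation(
            session.outcomes, alpha, _initial_estimate(session)
        )
        return _estimation_logliks(
            est, session.responses, grid, beta, 1.0 / (2.0 * sd * sd)
        )
    qmat = _replay_fixed_bandit(
        session.responses, session.outcomes, alpha, session.environment.n_arms
    )
    return _bandit_logliks(qmat, session.responses, beta)


def trial_logliks_bayes(
    beta: float,
    session: SessionRecord,
    assumed_hazard: float | None = None,
    assumed_noise_sd: float | None = None,
) -> np.ndarray:
    """Per-trial log-likelihood of the maximally adaptive (Bayes) model.

    The internal estimate follows the reduced Bayesian observer; the
    inverse temperature is the only free parameter.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    _check_session(session)
    h = session.agent.assumed_hazard if assumed_hazard is None else assumed_hazard
    sd = session.agent.assumed_noise_sd if assumed_noise_sd is None else assumed_noise_sd
    if session.task_kind == "estimation":
        grid = prediction_grid(session.environment.outcome_range, _GRID_STEP)
        est = _replay_bayes_estimation(
            session.outcomes, h, sd, session.environment.outcome_range,
            _initial_estimate(session),
        )
        return _estimation_logliks(
            est, session.responses, grid, beta, 1.0 / (2.0 * sd * sd)
        )
    qmat = _replay_bayes_bandit(
        session.responses, session.outcomes, session.environment.n_arms, h, sd
    )
    return _bandit_logliks(qmat, session.responses, beta)


# ---------------------------------------------------------------------------
# MLE driver


def _null_loglik_per_trial(session: SessionRecord) -> float:
    if session.task_kind == "bandit":
        return float(np.log(1.0 / session.environment.n_arms))
    g = prediction_grid(session.environment.outcome_range, _GRID_STEP).size
    return float(np.log(1.0 / g))


class _Objective:
    """Negative pooled log-likelihood over sessions, in transformed coords.

    For the Bayes model the belief trajectory does not depend on beta,
    so it is replayed once per session and cached.
    """

    def __init__(
        self,
        model_id: str,
        sessions: list[SessionRecord],
        masks: list[np.ndarray],
        assumed_hazard: float | None,
        assumed_noise_sd: float | None,
    ):
        self.model_id = model_id
        self.sessions = sessions
        self.masks = masks
        self._cache: list[dict] = []
        for s in sessions:
            item: dict = {"task": s.task_kind}
            if s.task_kind == "estimation":
                sd = assumed_noise_sd or s.agent.assumed_noise_sd
                item["grid"] = prediction_grid(s.environment.outcome_range, _GRID_STEP)
                item["inv_2s2"] = 1.0 / (2.0 * sd * sd)
                item["e0"] = _initial_estimate(s)
            if model_id == "bayes_lr":
                h = s.agent.assumed_hazard if assumed_hazard is None else assumed_hazard
                sd = (
                    s.agent.assumed_noise_sd
                    if assumed_noise_sd is None
                    else assumed_noise_sd
                )
                if s.task_kind == "estimation":
                    item["est"] = _replay_bayes_estimation(
                        s.outcomes, h, sd, s.environment.outcome_range, item["e0"]
                    )
                else:
                    item["qmat"] = _replay_bayes_bandit(
                        s.responses, s.outcomes, s.environment.n_arms, h, sd
                    )
            self._cache.append(item)

    def untransform(self, theta: np.ndarray) -> dict[str, float]:
        if self.model_id == "fixed_lr":
            return {"alpha": float(expit(theta[0])), "beta": float(np.exp(theta[1]))}
        if self.model_id == "bayes_lr":
            return {"beta": float(np.exp(theta[0]))}
        return {}

    def transform(self, params: dict[str, float]) -> np.ndarray:
        if self.model_id == "fixed_lr":
            a = np.clip(params["alpha"], 1e-9, 1 - 1e-9)
            return np.array([logit(a), np.log(max(params["beta"], 1e-12))])
        return np.array([np.log(max(params["beta"], 1e-12))])

    def session_logliks(self, params: dict[str, float], i: int) -> np.ndarray:
        s, c = self.sessions[i], self._cache[i]
        beta = params["beta"]
        if self.model_id == "fixed_lr":
            if s.task_kind == "estimation":
                est = _replay_fixed_estimation(s.outcomes, params["alpha"], c["e0"])
                return _estimation_logliks(
                    est, s.responses, c["grid"], beta, c["inv_2s2"]
                )
            qmat = _replay_fixed_bandit(
                s.responses, s.outcomes, params["alpha"], s.environment.n_arms
            )
            return _bandit_logliks(qmat, s.responses, beta)
        # bayes_lr: cached trajectories
        if s.task_kind == "estimation":
            return _estimation_logliks(
                c["est"], s.responses, c["grid"], beta, c["inv_2s2"]
            )
        return _bandit_logliks(c["qmat"], s.responses, beta)

    def __call__(self, theta: np.ndarray) -> float:
        params = self.untransform(theta)
        total = 0.0
        for i, m in enumerate(self.masks):
            ll = self.session_logliks(params, i)
            total += float(ll[m].sum())
        return -total


def _numerical_hessian(fun, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(theta)
    hess = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(theta))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        for j in range(i, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            if i == j:
                fpp = fun(theta + ei)
                fmm = fun(theta - ei)
                hess[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
            else:
                fpp = fun(theta + ei + ej)
                fpm = fun(theta + ei - ej)
                fmp = fun(theta - ei + ej)
                fmm = fun(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * steps[i] * steps[j]
                )
    return hess


def _numerical_gradient(fun, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = len(theta)
    grad = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h * max(1.0, abs(theta[i]))
        grad[i] = (fun(theta + e) - fun(theta - e)) / (2 * e[i])
    return grad


def _initial_points(
    n: int, n_params: int, seed: int, extra: list[np.ndarray]
) -> list[np.ndarray]:
    """Quasi-random starts: alpha uniform in (0.03, 0.97) on the logit
    scale, beta log-uniform on [0.05, 50]."""
    from scipy.stats import qmc

    pts: list[np.ndarray] = list(extra)
    if n > 0:
        sob = qmc.Sobol(d=max(n_params, 1), scramble=True, rng=np.random.default_rng(seed))
        u = sob.random(int(2 ** np.ceil(np.log2(n))))[:n]
        for row in u:
            if n_params == 2:
                a = 0.03 + 0.94 * row[0]
                b = np.exp(np.log(0.05) + row[1] * (np.log(50.0) - np.log(0.05)))
                pts.append(np.array([logit(a), np.log(b)]))
            elif n_params == 1:
                b = np.exp(np.log(0.05) + row[0] * (np.log(50.0) - np.log(0.05)))
                pts.append(np.array([np.log(b)]))
    return pts


def fit_mle(
    model_id: str,
    sessions: SessionRecord | Sequence[SessionRecord],
    include_masks: Sequence[np.ndarray] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    assumed_hazard: float | None = None,
    assumed_noise_sd: float | None = None,
    extra_starts: Sequence[dict[str, float]] | None = None,
    n_polish: int = 3,
    exclusion_window: int = 0,
) -> FitResult:
    """Fit a model to one or more sessions by pooled maximum likelihood.

    Parameters are optimized in unconstrained coordinates (alpha via
    logit, beta via log).  ``n_restarts`` quasi-random starting points
    are screened by objective value; Nelder-Mead runs from the best
    ``n_polish`` of them and the winner is polished with BFGS so the
    gradient at the returned optimum is numerically zero.  Standard
    errors and the parameter covariance come from the inverse numerical
    Hessian, delta-method mapped to the natural scale.

    ``include_masks`` selects the trials whose log-likelihood enters the
    objective (True = included); the model still updates through
    excluded trials.  An all-False mask raises, since the likelihood
    would be empty.

    ``extra_starts`` (natural-scale parameter dicts) are prepended to
    the start list; they count toward the screened candidates but not
    toward ``n_restarts``.
    """
    if model_id not in MODEL_PARAM_NAMES:
        raise ValueError(f"unknown model_id {model_id!r}")
    if isinstance(sessions, SessionRecord):
        sessions = [sessions]
    sessions = list(sessions)
    if not sessions:
        raise ValueError("at least one session is required")
    kinds = {s.task_kind for s in sessions}
    if len(kinds) > 1:
        raise ValueError("sessions must share a task kind")

    if include_masks is None:
        masks = [np.ones(s.n_trials, dtype=bool) for s in sessions]
    else:
        masks = [np.asarray(m, dtype=bool) for m in include_masks]
        if len(masks) != len(sessions):
            raise ValueError("one include_mask per session is required")
        for s, m in zip(sessions, masks):
            if len(m) != s.n_trials:
                raise ValueError("include_mask length must match n_trials")
    n_obs = int(sum(m.sum() for m in masks))
    if n_obs == 0:
        raise ValueError("all trials excluded: the likelihood is empty")

    param_names = MODEL_PARAM_NAMES[model_id]
    k = len(param_names)

    if model_id == "null":
        loglik = float(
            sum(m.sum() * _null_loglik_per_trial(s) for s, m in zip(sessions, masks))
        )
        return FitResult(
            model_id="null",
            params={},
            loglik=loglik,
            n_obs=n_obs,
            aic=-2.0 * loglik,
            bic=-2.0 * loglik,
            stderr={},
            covariance=np.empty((0, 0)),
            converged=True,
            n_restarts=0,
            exclusion_window=exclusion_window,
            param_names=(),
        )

    obj = _Objective(model_id, sessions, masks, assumed_hazard, assumed_noise_sd)
    extra = [obj.transform(p) for p in (extra_starts or [])]
    starts = _initial_points(n_restarts, k, seed, extra)

    scored = sorted(starts, key=lambda th: obj(th))
    best_x, best_f = None, np.inf
    n_runs = max(1, min(n_polish, len(scored)))
    any_success = False
    for th0 in scored[:n_runs]:
        res = optimize.minimize(
            obj,
            th0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxfev": 400},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        any_success = any_success or bool(res.success)
    # derivative-based polish: drives the gradient to numerical zero
    polish = optimize.minimize(obj, best_x, method="BFGS", options={"gtol": 1e-6})
    if polish.fun <= best_f:
        best_x, best_f = polish.x, polish.fun

    grad = _numerical_gradient(obj, best_x)
    converged = bool(np.max(np.abs(grad)) < 1e-3) or any_success

    hess = _numerical_hessian(obj, best_x)
    try:
        cov_t = np.linalg.pinv(hess)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov_t = np.full((k, k), np.nan)
    params = obj.untransform(best_x)
    # delta method: d(alpha)/d(logit alpha) = alpha (1 - alpha); d(beta)/d(log beta) = beta
    jac = np.diag(
        [
            params["alpha"] * (1 - params["alpha"])
            if name == "alpha"
            else params["beta"]
            for name in param_names
        ]
    )
    cov = jac @ cov_t @ jac.T
    stderr = {
        name: float(np.sqrt(max(cov[i, i], 0.0)))
        for i, name in enumerate(param_names)
    }

    loglik = -best_f
    aic = 2.0 * k - 2.0 * loglik
    bic = k * np.log(n_obs) - 2.0 * loglik
    return FitResult(
        model_id=model_id,
        params=params,
        loglik=loglik,
        n_obs=n_obs,
        aic=float(aic),
        bic=float(bic),
        stderr=stderr,
        covariance=cov,
        converged=converged,
        n_restarts=n_restarts,
        exclusion_window=exclusion_window,
        param_names=param_names,
    )
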