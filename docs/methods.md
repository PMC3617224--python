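# Methods

`deltadiag` is a simulation-and-fitting pipeline for studying what happens
when delta-rule models with a *fixed* learning rate are fit to behavior
generated with an *adaptive* learning rate, and for diagnosing that
misspecification. This note documents the models, the study conditions the
synthetic generators emulate, the numerical choices, and the limits of what
the simulations can show.

## Tasks

**Estimation task.** On each trial the subject predicts the next number in a
series. Outcomes are drawn from Normal(μ, σ²) with σ = 20 on the range
[0, 300]; with per-trial hazard H = 0.1 the latent mean μ resets to a fresh
uniform draw on the range. Outcomes falling outside the range are
*resampled* (rejection given the latent mean), not clipped, so the Gaussian
outcome model stays exact in the interior and the boundary atoms that
clipping would create never arise. Trial 0 counts as a change-point (the
first mean is a fresh draw), which anchors all change-point alignment
bookkeeping.

**Four-choice bandit task.** Four arms pay Bernoulli rewards with
probabilities {0.8, 0.4, 0.2, 0.1}; with hazard H = 0.04 the arm→probability
assignment is redrawn as a uniformly random permutation constrained to
differ from the previous one, so every flagged change-point is a real
contingency change. Hazards, ranges and probability sets are config-exposed;
the defaults make change-points rare relative to the learning timescale and
give the bandit one clearly best arm.

None of these constants are published values from any specific dataset; they
are the package's reference conditions, chosen once to be representative of
this task family.

## Agents

All agents share the delta-rule core

    E ← E + α_t (x_t − E),

and differ only in where α_t comes from:

    α_t = (1 − λ) α_fixed + λ α_bayes,t,

a convex blend controlled by the **adaptiveness** parameter λ ∈ [0, 1]. At
λ = 0 the update path is bit-identical to a fixed-rate delta rule (verified
against an independently coded reference to 1e−12); at λ = 1 it is the
reduced Bayesian observer below. The blend is the simplest parameterization
satisfying both endpoint constraints; other interpolations (e.g. blending in
log-odds) would be defensible but were not needed.

**Reduced Bayesian observer.** The observer tracks a point estimate E and an
expected run length r (trials since the last inferred change). After each
outcome it computes a change-point probability by a two-hypothesis Bayes
rule — change (outcome from the uniform density u on the outcome range)
versus no change (outcome from the Gaussian predictive with variance
σ²(1 + 1/r)):

    Ω = H·u / (H·u + (1 − H)·g),      g = N(x; E, σ²(1 + 1/r))
    α_bayes = Ω + (1 − Ω)/(r + 1)
    r′ = (r + 1)(1 − Ω) + Ω.

r is initialized at 1, which keeps the predictive variance finite and makes
the first update a half-weight average. The observer's assumed hazard and
noise default to the generative truth.

**Bandit variant.** The same machinery is driven by the chosen arm's
Bernoulli prediction error, with the uniform alternative density equal to 1
on [0, 1]. The Gaussian predictive uses the belief-dependent Bernoulli
variance Q(1 − Q), floored at (0.2)² so near-certain beliefs cannot make the
predictive degenerate. The floor value is `assumed_noise_sd` in the agent
configuration. A fixed predictive SD was tried first and rejected during
design: it makes the observer insensitive to reward omissions from
high-valued arms, and the resulting "maximally adaptive" model is then
*smoother* than a fixed-α = 0.3 learner, which inverts the qualitative
behavior of the adaptive-model fits. Only the chosen arm's value is updated;
unchosen arms are neither decayed nor updated.

**Action selection** is soft-max with inverse temperature β in both tasks.
In the bandit, choice probabilities are softmax(β·Q). In the estimation
task the emitted prediction is a soft-max draw over the integer grid of the
outcome range with quadratic utility −(p − E)²/(2σ²) — i.e. a discretized
Gaussian response distribution centered on the current estimate whose width
is σ/√β. This makes β interpretable as response precision and keeps the
response-model entropy independent of the estimate, a property that turns
out to matter for the diagnostics (below).

## Reference conditions

Six sessions of 800 trials per condition; adaptiveness grid
{0, 0.25, 0.5, 0.75, 1}; generative α_fixed = 0.3; two exploration levels
per task, β ∈ {0.5, 4} (estimation) and β ∈ {5, 10} (bandit). The β levels
were set during design-time calibration so that both levels clearly express
the phenomena under study (a β so low that behavior is near-random expresses
everything weakly); they were fixed before the test suite existed and not
revisited. Environments are shared across agent conditions within a sweep
(common random numbers); every environment and agent seed is derived from
one master seed via `SeedSequence` with CRC32-stable tags, so complete
experiment reruns are byte-identical.

## Fitting

Three models are fit to recorded responses by maximum likelihood, pooling
log-likelihoods across a subject's sessions (the pooled-fit convention was
chosen over per-session fits; with six homogeneous sessions the difference
is a scale factor on the information):

* **fixed_lr** — fixed-α delta rule + soft-max; free parameters (α, β);
* **bayes_lr** — reduced Bayesian observer (λ = 1); free parameter β;
* **null** — uniformly random choice; no parameters.

Fitted replays start from the same initial beliefs used generatively (range
midpoint for estimation, 0.5 per arm for the bandit); initial belief is not
a free parameter. Optimization runs in unconstrained coordinates (logit α,
log β): `n_restarts` quasi-random (scrambled Sobol) starting points are
screened by objective value, Nelder-Mead runs from the best three, and the
winner is polished with BFGS on a numerical gradient. The polish is what
drives the gradient at the returned optimum to < 1e−4 — simplex termination
alone cannot guarantee that at log-likelihood magnitudes of ~10³. Standard
errors and parameter covariance come from the inverse numerical Hessian
(central differences, relative step 1e−4) mapped to the natural scale by the
delta method; confidence intervals are Wald. Degenerate inputs raise:
an all-excluded trial mask (empty likelihood), responses off the grid,
mixed task kinds in one pooled fit.

Excluded trials contribute nothing to the objective, but the model still
*updates through* them, so exclusion perturbs only the likelihood, never the
belief trajectory.

## Diagnostics

* **Direct measurement** (estimation task only): α̂_t = (p_{t+1} − p_t)/(x_t −
  p_t) from raw predictions; trials with |prediction error| < 1 grid unit
  are flagged undefined rather than allowed to blow up the ratio.
* **Aligned likelihood profiles**: per-trial log-likelihoods of a fitted
  model averaged by trials-since-change-point (offset 0 = the change trial),
  using ground-truth change flags; offsets beyond 10 pool into a terminal
  steady-state bin. Sessions are aligned individually and trials then pooled.
* **Exclusion refits**: refit while dropping offsets 0..w after every
  change-point, w = 0..10, masks built per session before pooling. Refits
  are warm-started from the previous window's optimum (plus fresh random
  starts), which stabilizes the curve and lets the sweep run with fewer cold
  restarts (4) than a cold fit (10).

A structural caveat discovered with this pipeline: in the bandit task the
aligned profile of even a *correctly specified* model is depressed for many
trials after a change-point, because the agent's value estimates compress
and its own choice entropy rises — the steady-state bin is elevated for
reasons unrelated to misfit. The estimation task does not have this
confound (its response entropy is independent of the estimate), which is
part of why post-change likelihood inspection is diagnostic there and not in
the bandit. Consequently, "offset-1 equals the steady state" is not a sound
null expectation for the bandit profile; the sound expectation is the
*absence of a pronounced offset-1 minimum*.

## Problem sizes

The bias and diagnostics experiments and the acceptance script run at the
full reference conditions (6 × 800 trials per condition). The
byte-determinism contract is exercised at a reduced size (2 sessions × 200
trials, two adaptiveness levels) since the property is scale-free.

## Known limitations

* The observer reconstructions (run-length point estimate, Gaussian/uniform
  two-hypothesis rule, convex adaptiveness blend) are one member of a family
  of adaptive-learning models; conclusions about *which* diagnostics work
  are qualitative and should transfer within the family, but exact fitted
  values are reconstruction-specific.
* Synthetic behavior contains none of the other known nuisance processes in
  real choice data (choice perseveration, lapses, reaction-time coupling,
  drifting attention). Passing tests therefore demonstrate properties of the
  inference machinery under the stated generative assumptions, not the
  magnitude of biases in any real dataset.
* Model comparison is information-criterion based; cross-validation and
  Bayesian posterior estimation are out of scope.
* Wald intervals from a numerical Hessian can be optimistic near the α → 0/1
  boundaries; none of the reference conditions put the optimum there.
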