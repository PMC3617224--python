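"""The core phenomenon: fitting a fixed learning-rate model to agents
whose learning rate is actually adaptive.

Sweeps the adaptiveness blend from 0 (fixed delta rule) to 1 (reduced
Bayesian observer) on the estimation task, and compares the learning
rates the agents actually used with the values a fixed-LR model infers
— together with the fitted inverse temperature, which absorbs the
unmodeled variability and drifts downward.
"""

import numpy as np

from deltadiag import (
    AgentConfig,
    fit_mle,
    generate_changepoint_series,
    simulate_estimation_session,
)

BETA_GEN = 2.0
series = [generate_changepoint_series(800, seed=10 + i) for i in range(3)]

print(f"{'lam':>5} {'realized alpha':>15} {'fitted alpha':>13} {'fitted beta':>12}")
for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
    sessions = [
        simulate_estimation_session(
            s, AgentConfig(0.3, lam, BETA_GEN, 0.1, 20.0, seed=50 + 7 * int(lam * 100) + i)
        )
        for i, s in enumerate(series)
    ]
    med = np.median(np.concatenate([s.realized_alphas for s in sessions]))
    fit = fit_mle("fixed_lr", sessions, seed=3)
    print(
        f"{lam:>5.2f} {med:>15.3f} {fit.params['alpha']:>13.3f} "
        f"{fit.params['beta']:>12.3f}"
    )

print(
    f"\nGenerative inverse temperature was {BETA_GEN:g} throughout.  As"
    "\nadaptiveness grows, the realized learning rate falls while the fitted"
    "\none rises (post-change bursts dominate the likelihood), and the fitted"
    "\ninverse temperature sinks below truth — adaptive learning masquerading"
    "\nas extra exploration."
)
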