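import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deltadiag.agents import (
    AgentConfig,
    simulate_bandit_session,
    simulate_estimation_session,
)
from deltadiag.tasks import generate_bandit_schedule, generate_changepoint_series

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_series():
    """A 400-trial estimation environment."""
    return generate_changepoint_series(400, seed=17)


@pytest.fixture(scope="session")
def small_schedule():
    """A 400-trial four-arm bandit schedule."""
    return generate_bandit_schedule(400, seed=17)


@pytest.fixture(scope="session")
def est_session_fixed(small_series):
    """Estimation session from a pure fixed-rate agent (lam=0)."""
    agent = AgentConfig(alpha_fixed=0.3, adaptiveness=0.0, beta=2.0, seed=23)
    return simulate_estimation_session(small_series, agent)


@pytest.fixture(scope="session")
def est_session_adaptive(small_series):
    """Estimation session from a fully adaptive agent (lam=1)."""
    agent = AgentConfig(alpha_fixed=0.3, adaptiveness=1.0, beta=2.0, seed=29)
    return simulate_estimation_session(small_series, agent)


@pytest.fixture(scope="session")
def bandit_session_fixed(small_schedule):
    agent = AgentConfig(
        alpha_fixed=0.3, adaptiveness=0.0, beta=5.0,
        assumed_hazard=0.04, assumed_noise_sd=0.2, seed=23,
    )
    return simulate_bandit_session(small_schedule, agent)


@pytest.fixture(scope="session")
def bandit_session_adaptive(small_schedule):
    agent = AgentConfig(
        alpha_fixed=0.3, adaptiveness=1.0, beta=5.0,
        assumed_hazard=0.04, assumed_noise_sd=0.2, seed=29,
    )
    return simulate_bandit_session(small_schedule, agent)
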