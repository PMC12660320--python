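import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import revlearn as rl

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_schedule():
    """One materialised study-scale schedule (320 trials, 4 blocks)."""
    return rl.build_schedule(rl.TaskConfig(seed=123))


@pytest.fixture(scope="session")
def rw2_session(default_schedule):
    """A typical RW2 agent session on the default schedule."""
    params = rl.AgentParams(model_id="RW2", alpha_pos=0.5, alpha_neg=0.3, beta=6.0)
    trials = rl.simulate_agent(params, default_schedule, lost_rate=0.02, seed=7)
    return params, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
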