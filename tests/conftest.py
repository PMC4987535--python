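import numpy as np
import pytest

from twostage.agents import AgentParams, simulate_agent
from twostage.task_engine import TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mid_params():
    return AgentParams(alpha=0.5, beta=4.0, lam=0.5, p_stick=0.2, w=0.5, v=0.2)


@pytest.fixture(scope="session")
def small_session(mid_params):
    """One 60-trial condition-1 session from a mid-range agent."""
    config = TaskConfig(n_trials=60, condition=1, seed=42)
    trials, trace = simulate_agent(
        mid_params, config, rng=np.random.default_rng(42), subject_id="s0"
    )
    return trials, trace


@pytest.fixture(scope="session")
def cond2_session(mid_params):
    config = TaskConfig(n_trials=60, condition=2, seed=43)
    trials, trace = simulate_agent(
        mid_params, config, rng=np.random.default_rng(43), subject_id="s0"
    )
    return trials, trace
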