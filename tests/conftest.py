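import numpy as np
import pytest

from noveltybandit.agent import AgentParams, simulate_agent
from noveltybandit.model_fit import derive_trajectory
from noveltybandit.task_env import TaskConfig, generate_schedule


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def schedule(default_config):
    return generate_schedule(default_config, seed=42)


@pytest.fixture(scope="session")
def dataset(schedule):
    return simulate_agent(schedule, AgentParams(alpha=0.692, beta=8.0), seed=7)


@pytest.fixture(scope="session")
def trajectory(dataset):
    return derive_trajectory(dataset, alpha=0.692)


@pytest.fixture(scope="session")
def agent_cohort():
    """Twenty simulated agents on distinct schedules (shared study params)."""
    rng = np.random.default_rng(2024)
    out = []
    for i in range(20):
        sched = generate_schedule(TaskConfig(), int(rng.integers(2**31)))
        out.append(
            simulate_agent(
                sched, AgentParams(alpha=0.692, beta=8.0), int(rng.integers(2**31)),
                subject_id=f"sub-{i:02d}",
            )
        )
    return out
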