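import numpy as np
import pytest

from seqreach.behavior_sim import AgentParams, MovementParams, simulate_session
from seqreach.session_io import Phase
from seqreach.task_engine import TargetLayout, TaskConfig, TaskMode


@pytest.fixture
def layout() -> TargetLayout:
    return TargetLayout()


@pytest.fixture
def task_configs() -> list[TaskConfig]:
    return [
        TaskConfig(mode=TaskMode.RANDOM),
        TaskConfig(mode=TaskMode.REPEATING, sequence=(5, 3, 1)),
        TaskConfig(mode=TaskMode.RANDOM),
        TaskConfig(mode=TaskMode.REPEATING, sequence=(1, 2, 4)),
    ]


@pytest.fixture
def quiet_agent() -> AgentParams:
    """A well-trained agent: high predictive rate, modest endpoint noise."""
    return AgentParams(
        default=MovementParams(p_predictive=0.9, endpoint_sigma=12.0)
    )


def make_session(
    task_configs,
    layout,
    agent,
    *,
    effect=None,
    phase=Phase.PRE,
    n_trials=400,
    seed=0,
    block_length_range=(100, 150),
):
    """Small-session helper used across test modules."""
    return simulate_session(
        task_configs,
        layout,
        agent,
        effect=effect,
        phase=phase,
        n_trials=n_trials,
        seed=seed,
        block_length_range=block_length_range,
    )
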