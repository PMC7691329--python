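import numpy as np
import pytest

from orientrack.simulate import AgentParams, CalciumSimParams, simulate_behavior_cohort, simulate_calcium_session
from orientrack.task import TaskConfig


@pytest.fixture(scope="session")
def opto_task() -> TaskConfig:
    """Final-stage task config for optogenetic sessions (random cues, 30% laser)."""
    return TaskConfig(contingency="inward", laser_fraction=0.3, anti_bias=False)


@pytest.fixture(scope="session")
def null_cohort(opto_task):
    """Six-mouse cohort with no laser effect (fast, traceless)."""
    agent = AgentParams(laser_delta_contra=0.0)
    sessions, gt = simulate_behavior_cohort(
        agent, opto_task, n_mice=6, n_sessions=3, trials_per_session=300, seed=101, traces=False
    )
    return sessions, gt


@pytest.fixture(scope="session")
def effect_cohort(opto_task):
    """Cohort with an injected +0.2 contraversive-action laser effect."""
    agent = AgentParams(laser_delta_contra=0.2)
    sessions, gt = simulate_behavior_cohort(
        agent, opto_task, n_mice=6, n_sessions=3, trials_per_session=300, seed=102, traces=False
    )
    return sessions, gt


@pytest.fixture(scope="session")
def imaging_session(opto_task):
    """One traceless behavioral session plus its synthetic calcium data."""
    agent = AgentParams(p_correct_right=0.75, p_correct_left=0.75)
    sessions, _ = simulate_behavior_cohort(
        agent, TaskConfig(anti_bias=False), n_mice=1, n_sessions=1,
        trials_per_session=150, seed=103, traces=False,
    )
    params = CalciumSimParams(n_neurons=40, ipsi_bias=0.3)
    traces, gt = simulate_calcium_session(sessions[0], params, seed=104)
    return sessions[0], traces, gt
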