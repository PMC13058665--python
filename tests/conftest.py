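import numpy as np
import pytest

import rebl
from rebl import task


@pytest.fixture
def default_config() -> rebl.TaskConfig:
    return rebl.build_task_config({}, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def always_advantageous(block, history):
    return task.ADVANTAGEOUS


def always_disadvantageous(block, history):
    return task.DISADVANTAGEOUS


@pytest.fixture
def advantageous_session(default_config, rng) -> rebl.SessionData:
    return task.run_session(always_advantageous, default_config, rng)


@pytest.fixture
def agent_session(default_config) -> rebl.SessionData:
    """A representative simulated learner (counterfactual alpha+tau model)."""
    params = rebl.ParameterVector(alpha=0.44, tau=1.5)
    spec = rebl.get_model("cf_alpha_tau")
    return rebl.simulate_agent(params, spec, default_config, np.random.default_rng(7))
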