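import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from arbrl import AgentParams, TaskConfig, TaskGraph, build_design
from arbrl.cohort import simulate_dataset


@pytest.fixture(scope="session")
def graph():
    return TaskGraph()


@pytest.fixture(scope="session")
def default_design():
    return build_design(TaskConfig(), seed=1)


@pytest.fixture(scope="session")
def default_params():
    return AgentParams()


@pytest.fixture(scope="session")
def hc_log(default_design, default_params):
    """One simulated subject on the default six-session design."""
    return simulate_dataset(default_params, default_design, seed=2, subject="fix0")


@pytest.fixture(scope="session")
def short_design():
    """Two sessions, no pretraining: 80 trials, quick to simulate."""
    cfg = TaskConfig(sessions=2, pretrain_trials=0, pretrain_universal=0)
    return build_design(cfg, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
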