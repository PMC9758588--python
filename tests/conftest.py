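import numpy as np
import pytest

from sampeeg.agents import AgentParams, simulate_session
from sampeeg.design import build_session


@pytest.fixture(scope="session")
def small_session():
    return build_session(n_trials=40, n_blocks=5, rng_seed=11)


@pytest.fixture(scope="session")
def partial_trials(small_session):
    """One synthetic participant's fixed-length (12-sample) trials."""
    rng = np.random.default_rng(21)
    params = AgentParams(side_policy="random")
    return simulate_session(params, small_session, "partial", rng)


@pytest.fixture(scope="session")
def full_trials(small_session):
    rng = np.random.default_rng(22)
    params = AgentParams(side_policy="random")
    return simulate_session(params, small_session, "full", rng)
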