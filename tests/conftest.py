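import numpy as np
import pytest

from beadsampling.simulate import AgentProfile, make_schedule, simulate_agent


@pytest.fixture(scope="session")
def schedule():
    return make_schedule(permutation_id=1, rng=0)


@pytest.fixture(scope="session")
def cost_first_trials(schedule):
    """One simulated session from a pure cost-first agent."""
    profile = AgentProfile("A1", aq=70, pi_costfirst=1.0, seed=1)
    return simulate_agent(profile, schedule, rng=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
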