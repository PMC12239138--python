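import pytest

from neuroarena import arena_sim, associative_net as anet


@pytest.fixture(scope="session")
def net_cfg() -> anet.NetworkConfig:
    return anet.NetworkConfig()


@pytest.fixture(scope="session")
def arena_cfg() -> arena_sim.ArenaConfig:
    return arena_sim.ArenaConfig()


@pytest.fixture(scope="session")
def conditioned_network(net_cfg):
    """One four-phase-conditioned network shared across behavioural tests
    (trials always run on copies, so sharing is safe)."""
    state, trace = anet.condition_network(net_cfg, n_pairings=15, record=True)
    return state, trace
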