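import pytest

from timegrn import SimConfig, discover_from_sim, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """The reference synthetic scenario (seed 0)."""
    return simulate_all(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_result(default_sim):
    """Full pipeline output on the reference scenario."""
    return discover_from_sim(default_sim)
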