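import pytest

from cofunnet import synthdata as sd
from cofunnet.types import GeneNetwork


@pytest.fixture
def triangle() -> GeneNetwork:
    net = GeneNetwork()
    net.add("a", "b", 1.0)
    net.add("b", "c", 2.0)
    net.add("a", "c", 3.0)
    return net


@pytest.fixture(scope="session")
def default_spec() -> sd.SynthSpec:
    return sd.SynthSpec(seed=11)


@pytest.fixture(scope="session")
def recovery(default_spec) -> sd.RecoveryFixture:
    """One fully calibrated and integrated toy world, shared across tests."""
    return sd.recovery_fixture(default_spec)


@pytest.fixture(scope="session")
def recovery_sweep() -> list[sd.RecoveryFixture]:
    """Ten independent seeds of the end-to-end pipeline (statistical checks)."""
    return [sd.recovery_fixture(sd.SynthSpec(seed=100 + s)) for s in range(10)]
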