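import numpy as np
import pytest

from gcn4set import ScanParams, UtrLayout


@pytest.fixture(scope="session")
def layout():
    return UtrLayout()


@pytest.fixture(scope="session")
def repressed():
    return ScanParams.repressed()


@pytest.fixture(scope="session")
def derepressed():
    return ScanParams.derepressed()


@pytest.fixture(scope="session")
def wild_type_events():
    """A moderately sized wild-type acquisition shared across tests."""
    from gcn4set import SynthConfig, generate_events

    return generate_events(SynthConfig(n_events=50_000, seed=1101))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_001)
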