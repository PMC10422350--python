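import numpy as np
import pytest

from lungsig import SimulationConfig, generate_recording


@pytest.fixture(scope="session")
def three_cycle_recording():
    """A short noiseless deep-breathing recording shared across tests."""
    return generate_recording(SimulationConfig(n_cycles=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230790)
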