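import numpy as np
import pytest

from swarmotility.presets import make_preset
from swarmotility.synthetic import simulate_population


@pytest.fixture(scope="session")
def liquid_population():
    """100 liquid-preset cells, 100 s at 10 fps (shared across tests)."""
    return simulate_population(make_preset("liquid"), 100, 100.0, 0.1, seed=42)


@pytest.fixture(scope="session")
def swarm_population():
    return simulate_population(make_preset("swarm"), 100, 100.0, 0.1, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
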