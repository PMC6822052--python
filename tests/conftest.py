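import numpy as np
import pytest

from floodnest import (
    EnvironmentRegime,
    LifeHistory,
    SimulationConfig,
    default_toy_pair,
)


@pytest.fixture(scope="session")
def toy_pair():
    return default_toy_pair()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast, small-population configuration for mechanistic tests."""
    return SimulationConfig(
        regime=EnvironmentRegime(p=0.1, s=0.9, h=0.4),
        life_history=LifeHistory(n=2, c=5.0),
        n0=60,
        k=60,
        generations=40,
        seed=99,
    )
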