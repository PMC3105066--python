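import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metanorms import GameConfig, InteractionNetwork, generate_er, generate_watts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return GameConfig()


@pytest.fixture(scope="session")
def k20():
    """Complete graph on 20 agents (vertex-transitive)."""
    return InteractionNetwork(20, itertools.combinations(range(20), 2))


@pytest.fixture(scope="session")
def ring50():
    """Regular ring lattice, 50 agents, degree 4 (vertex-transitive)."""
    return generate_watts(50, 4, 0.0, seed=1)


@pytest.fixture(scope="session")
def er50():
    """One fixed Erdős–Rényi draw, 50 agents, p = 0.1."""
    return generate_er(50, 0.1, seed=2)
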