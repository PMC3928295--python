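import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fragopt import DomainPartition, RunConfig
from fragopt.backends import MockBackend
from fragopt.fixtures import make_toy_reaction, make_water_chain


@pytest.fixture
def mock_backend():
    return MockBackend()


@pytest.fixture
def water3():
    """Three perturbed waters, all active: the standard gradient fixture."""
    geometry, fragments = make_water_chain(3, spacing=3.0, seed=7, perturbation=0.1)
    partition = DomainPartition(
        frozen=frozenset(),
        polarizable=frozenset(),
        active=frozenset({0, 1, 2}),
        high_level=0,
    )
    return geometry, fragments, partition


@pytest.fixture
def water3_config():
    return RunConfig(
        dimer_cutoff=1.5,
        polarization_enabled=True,
        hybrid_mp2=True,
        mp2_basis="cc-pVDZ",
    )


@pytest.fixture
def toy():
    return make_toy_reaction(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20140218)
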