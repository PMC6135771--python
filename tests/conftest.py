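import numpy as np
import pytest

from hairpinmc.cgmodel import (
    CGParameters,
    HairpinModel,
    build_extended_fixture,
    build_native_fixture,
)
from hairpinmc.topology import build_hairpin_topology


@pytest.fixture(scope="session")
def gb1p_topology():
    return build_hairpin_topology("GB1p")


@pytest.fixture(scope="session")
def native_frame(gb1p_topology):
    return build_native_fixture(gb1p_topology)


@pytest.fixture(scope="session")
def extended_frame(gb1p_topology):
    return build_extended_fixture(gb1p_topology)


@pytest.fixture(scope="session")
def gb1p_model(gb1p_topology):
    return HairpinModel(gb1p_topology, CGParameters())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
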