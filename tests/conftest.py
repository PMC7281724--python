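import numpy as np
import pytest

from spiralsort import (
    ChannelGeometry,
    MigrationModel,
    OutletChannel,
    OutletManifold,
    WATER,
)
from spiralsort.config import reference_device


@pytest.fixture(scope="session")
def geom() -> ChannelGeometry:
    """The reference 7-turn expanding-width spiral."""
    return ChannelGeometry()


@pytest.fixture(scope="session")
def model() -> MigrationModel:
    return MigrationModel()


@pytest.fixture(scope="session")
def fluid():
    return WATER


@pytest.fixture(scope="session")
def ref_config():
    return reference_device()


@pytest.fixture(scope="session")
def manifold(ref_config) -> OutletManifold:
    """Reconstructed four-outlet collection manifold of the reference device."""
    return ref_config.manifold.to_manifold()


def random_manifold(rng: np.random.Generator, n_outlets: int = 4) -> OutletManifold:
    """A random physically plausible manifold for property tests."""
    outlets = tuple(
        OutletChannel(
            index=i + 1,
            width_um=float(rng.uniform(50, 500)),
            height_um=float(rng.uniform(20, 200)),
            length_mm=float(rng.uniform(0.5, 100)),
        )
        for i in range(n_outlets)
    )
    return OutletManifold(outlets)
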