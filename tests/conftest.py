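import numpy as np
import pytest

from spineflow.config import PhantomConfig
from spineflow.core import VoxelGeometry
from spineflow.phantom import generate_phantom


@pytest.fixture
def unit_geometry():
    return VoxelGeometry(voxel_size=(1.0, 1.0, 1.0))


@pytest.fixture
def confocal_geometry():
    return VoxelGeometry()  # the anisotropic confocal spacing


@pytest.fixture(scope="session")
def phantom_pair():
    """One clean default phantom (no defects), shared across tests."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def broken_phantom_pair():
    """A phantom with half its spine necks erased from the labels."""
    return generate_phantom(PhantomConfig(seed=7, neck_break_probability=0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
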