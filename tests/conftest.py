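import numpy as np
import pytest

from synconn import load_default_catalog
from synconn.regions import VoxelGrid


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def mni_grid():
    """Standard 3-mm grid covering MNI space (61 x 73 x 61 voxels)."""
    return VoxelGrid.isotropic((61, 73, 61), 3.0, origin_mni=(-90.0, -126.0, -72.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
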