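import numpy as np
import pytest

from ulm3d.core import PSFModel, VoxelGrid


@pytest.fixture
def psf() -> PSFModel:
    return PSFModel()  # (0.4, 0.4, 0.17) mm


@pytest.fixture
def phantom_grid() -> VoxelGrid:
    """Post-interpolation-scale phantom grid (0.1 x 0.1 x 0.04 mm pitch)."""
    return VoxelGrid((0.0, 0.0, 0.0), (0.1, 0.1, 0.04), (48, 48, 48))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
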