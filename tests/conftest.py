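import numpy as np
import pytest

from engulf3d import BinaryMask3D, VoxelSize


@pytest.fixture
def voxel_20x():
    return VoxelSize(dx=0.3, dy=0.3, dz=0.67)


@pytest.fixture
def voxel_63x():
    return VoxelSize(dx=0.07, dy=0.07, dz=0.23)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.3, voxel=VoxelSize(0.3, 0.3, 0.67)):
    return BinaryMask3D(grid=rng.random(shape) < p, voxel=voxel)
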