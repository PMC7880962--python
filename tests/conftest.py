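import numpy as np
import pytest

from radbatch.image_io import ROIMask, VoxelGrid


def make_grid(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VoxelGrid(np.asarray(values, dtype=float), spacing, origin)


def make_mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ROIMask(np.asarray(values, dtype=bool), spacing, origin)


def random_roi(rng, max_side=8, hu_range=(0.0, 260.0), density=0.8):
    """Random small volume + mask with at least one guaranteed ROI voxel."""
    shape = tuple(int(s) for s in rng.integers(4, max_side + 1, size=3))
    values = rng.uniform(*hu_range, size=shape)
    mask = rng.random(shape) < density
    mask[tuple(s // 2 for s in shape)] = True
    return values, mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
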