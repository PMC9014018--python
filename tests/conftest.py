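import numpy as np
import pytest

from goldio.data_model import ParticlePointSet, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def full_mask():
    return RoiMask(grid=np.ones((100, 100), dtype=bool))


@pytest.fixture
def blob_mask():
    """Irregular 64x64 blob: union of two off-center disks."""
    r, c = np.mgrid[0:64, 0:64]
    grid = ((r - 22) ** 2 + (c - 25) ** 2 <= 18**2) | (
        (r - 40) ** 2 + (c - 42) ** 2 <= 14**2
    )
    return RoiMask(grid=grid)


@pytest.fixture
def triangle_points():
    return ParticlePointSet.from_points([(0, 0), (3, 4), (100, 100)])
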