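import numpy as np
import pytest

from mclrad.volumes import PETVolume


@pytest.fixture
def spacing_pet():
    """The scanner voxel spacing used throughout: 5.5 x 5.5 x 3.3 mm."""
    return (5.5, 5.5, 3.3)


@pytest.fixture
def cross_volume(spacing_pet):
    """3x3x3 volume: centre SUV 10, face neighbours SUV 5, corners/edges SUV 1."""
    grid = np.ones((3, 3, 3))
    grid[1, 1, 1] = 10.0
    for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        grid[1 + d[0], 1 + d[1], 1 + d[2]] = 5.0
    return PETVolume(grid=grid, spacing_mm=spacing_pet, patient_id="cross")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masked_volume(rng, max_shape=8, n_bins_max=8):
    """Random small quantized volume + mask for oracle comparisons."""
    shape = tuple(int(rng.integers(2, max_shape + 1)) for _ in range(3))
    n_bins = int(rng.integers(2, n_bins_max + 1))
    levels = rng.integers(1, n_bins + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask.flat[0] = True
    levels[~mask] = 0
    return levels, mask, n_bins
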