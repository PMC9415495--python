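import numpy as np
import pytest

from contour_agree.io_masks import BinaryMask, ImageVolume
from contour_agree.synthetic_data import PhantomSpec


def make_grid(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), origin=None):
    """A small test grid with axis-aligned affine."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    if origin is None:
        origin = [-(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    affine[:3, 3] = origin
    return ImageVolume(
        data=np.zeros(shape, dtype=float), spacing=spacing, affine=affine
    )


def mask_from_array(arr, grid=None, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=bool)
    if grid is None:
        grid = make_grid(arr.shape, spacing)
    return BinaryMask(data=arr, grid=grid)


def random_mask(rng, grid, p=0.3):
    return BinaryMask(data=rng.random(grid.shape) < p, grid=grid)


@pytest.fixture
def grid16():
    return make_grid((16, 16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_template():
    """Coarse phantom template for fast end-to-end tests."""
    return PhantomSpec(
        shape=(32, 32, 32),
        spacing=(4.0, 4.0, 4.0),
        brain_semi_axes_mm=(55.0, 60.0, 50.0),
        tumor_center_mm=(25.0, 5.0, 0.0),
        tumor_semi_axes_mm=(14.0, 12.0, 11.0),
    )
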