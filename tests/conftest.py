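import numpy as np
import pytest

from spinewarp.geometry import ImageVolume, Point3, StructureMask
from spinewarp.phantom import PhantomParams


def make_volume(shape=(6, 20, 20), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                fill=-1000.0):
    vox = np.full(shape, fill, dtype=np.float32)
    return ImageVolume(vox, spacing, Point3(*origin))


def centered_volume(shape=(8, 40, 40), spacing=(2.0, 2.0, 3.0)):
    """Volume whose physical grid is centred on the origin."""
    nz, ny, nx = shape
    dx, dy, dz = spacing
    origin = Point3(-dx * (nx - 1) / 2, -dy * (ny - 1) / 2, -dz * (nz - 1) / 2)
    return ImageVolume(np.full(shape, -1000.0, np.float32), spacing, origin)


def small_params(**overrides) -> PhantomParams:
    """Desk-scale phantom grid used throughout the unit tests."""
    base = dict(shape=(24, 64, 64), spacing=(3.0, 3.0, 4.0))
    base.update(overrides)
    return PhantomParams(**base)


def zero_gap_params(**overrides) -> PhantomParams:
    zero = dict(
        sag_depth=0.0,
        sigma_pat=0.0,
        sys_coeffs={"x": (0, 0, 0), "y": (0, 0, 0), "z": (0, 0, 0)},
        contour_noise_sd=0.0,
    )
    zero.update(overrides)
    return small_params(**zero)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def disk_mask(vol: ImageVolume, center_xy, radius, slices=None):
    xs = vol.x_coords()
    ys = vol.y_coords()
    X, Y = np.meshgrid(xs, ys)
    disk = (X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2 <= radius**2
    m = np.zeros(vol.shape, dtype=bool)
    for k in slices if slices is not None else range(vol.shape[0]):
        m[k] = disk
    return StructureMask("body", m)
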