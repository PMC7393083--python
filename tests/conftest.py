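import numpy as np
import pytest

from noduleseg.synthetic import PhantomSpec, generate_phantom
from noduleseg.volume_io import CTVolume, MaskVolume


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Convex noiseless ellipsoid phantom with exact ground truth."""
    spec = PhantomSpec(
        shape=(32, 64, 64),
        spacing=(1.0, 1.0, 1.0),
        semi_axes_mm=(6.0, 9.0, 7.0),
        lobulation=0.0,
        noise_sigma=0.0,
        seed=42,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mask_volume(rng, shape=(6, 7, 8), density=0.3, spacing=(1.0, 1.0, 1.0)) -> MaskVolume:
    return MaskVolume((rng.random(shape) < density).astype(np.uint8), spacing)


def ellipse_stack(
    rng,
    nz=16,
    ny=64,
    nx=64,
    base_r=(4.0, 9.0),
    drift=1.5,
):
    """Random slice sequence: an ellipse whose centre drifts and whose radii
    wax and wane across z, vanishing outside [z_lo, z_hi]. Returns
    (CTVolume, MaskVolume) with intensities equal to the mask."""
    mask = np.zeros((nz, ny, nx), dtype=np.uint8)
    z_lo = int(rng.integers(2, nz // 2))
    z_hi = int(rng.integers(nz // 2 + 1, nz - 2))
    cy, cx = rng.uniform(0.35 * ny, 0.65 * ny), rng.uniform(0.35 * nx, 0.65 * nx)
    ry0, rx0 = rng.uniform(*base_r), rng.uniform(*base_r)
    yy, xx = np.mgrid[0:ny, 0:nx]
    mid = 0.5 * (z_lo + z_hi)
    half = max(0.5 * (z_hi - z_lo), 0.5)
    for z in range(z_lo, z_hi + 1):
        # elliptic-profile radius shrink toward the ends
        f = np.sqrt(max(1.0 - ((z - mid) / (half + 0.5)) ** 2, 0.02))
        ry, rx = max(ry0 * f, 1.0), max(rx0 * f, 1.0)
        cy += rng.uniform(-drift, drift)
        cx += rng.uniform(-drift, drift)
        mask[z] = ((yy - cy) ** 2 / ry**2 + (xx - cx) ** 2 / rx**2 <= 1.0).astype(np.uint8)
        if mask[z].sum() == 0:  # guarantee at least one pixel per in-range slice
            mask[z, int(round(cy)) % ny, int(round(cx)) % nx] = 1
    vol = CTVolume(mask.astype(np.float32), (1.0, 1.0, 1.0), window_center=0.5, window_width=1.0)
    return vol, MaskVolume(mask, (1.0, 1.0, 1.0))
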