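"""Synthetic nodule phantoms with exact ground truth.

Real screening data pairs blob-like nodules of varying size, lobulation
and contrast with anisotropic CT grids (fine in-plane spacing, coarse
slice thickness), noisy parenchyma and occasionally an attached vessel.
This module fabricates volumes with those features and an *exact* voxel
ground-truth mask, plus an oracle segmenter test double that returns the
(optionally corrupted) truth inside any patch — so the geometric
pipeline can be exercised and measured with no external dataset and no
trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .aroi import PatchRef, Segmenter, SquareROI
from .volume_io import CTVolume, MaskVolume

_VIEW_CODE = {"axial": 0, "coronal": 1, "sagittal": 2}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic nodule phantom.

    Lengths are in millimetres; the nodule is a radially perturbed
    ellipsoid. ``lobulation`` in [0, 1) scales a smooth low-order
    angular perturbation of the radius; 0 gives an exact ellipsoid.
    ``cylinder_radius_mm`` > 0 attaches a tubular structure through the
    nodule centre (juxta-vascular case); the cylinder is part of the
    image but *not* of the ground-truth mask.
    """

    shape: tuple[int, int, int] = (48, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] | None = None
    semi_axes_mm: tuple[float, float, float] = (6.0, 8.0, 7.0)
    lobulation: float = 0.0
    contrast: float = 0.55
    background: float = 0.15
    texture_scale: float = 0.0
    noise_sigma: float = 0.0
    cylinder_radius_mm: float = 0.0
    cylinder_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    seed: int = 0


def _angular_perturbation(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random function of direction with values in [-1, 1].

    A small trigonometric expansion in the polar/azimuthal angles stands
    in for low-order spherical harmonics; it is C^inf in direction, so
    the perturbed boundary stays blob-like rather than spiky.
    """
    r = np.linalg.norm(u, axis=-1)
    r = np.maximum(r, 1e-9)
    theta = np.arccos(np.clip(u[..., 0] / r, -1.0, 1.0))  # polar from z
    phi = np.arctan2(u[..., 1], u[..., 2])  # azimuth in (y, x) plane
    coeffs = rng.normal(size=8)
    f = (
        coeffs[0] * np.cos(theta)
        + coeffs[1] * np.cos(2 * theta)
        + coeffs[2] * np.sin(theta) * np.cos(phi)
        + coeffs[3] * np.sin(theta) * np.sin(phi)
        + coeffs[4] * np.sin(theta) ** 2 * np.cos(2 * phi)
        + coeffs[5] * np.sin(theta) ** 2 * np.sin(2 * phi)
        + coeffs[6] * np.sin(2 * theta) * np.cos(phi)
        + coeffs[7] * np.sin(2 * theta) * np.sin(phi)
    )
    peak = max(float(np.abs(f).max()), 1e-9)
    return f / peak


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, MaskVolume]:
    """Build a phantom volume and its exact ground-truth mask.

    Deterministic per ``spec.seed``. Raises if the nodule does not fit
    inside the grid.
    """
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    extent_mm = np.array([nz * sz, ny * sy, nx * sx])
    center = (
        np.asarray(spec.center_mm, float)
        if spec.center_mm is not None
        else extent_mm / 2.0
    )
    semi = np.asarray(spec.semi_axes_mm, float)
    if (semi <= 0).any():
        raise ValueError(f"semi-axes must be positive, got {semi}")
    max_r = semi * (1.0 + spec.lobulation)
    if (center - max_r < 0).any() or (center + max_r > extent_mm).any():
        raise ValueError("nodule (incl. lobulation) does not fit inside the grid")

    rng = np.random.default_rng(spec.seed)

    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    grid = np.stack(np.meshgrid(zc, yc, xc, indexing="ij"), axis=-1) - center
    u = grid / semi
    rho = np.linalg.norm(u, axis=-1)

    if spec.lobulation > 0:
        pert = spec.lobulation * _angular_perturbation(u, rng)
    else:
        pert = 0.0
    mask = (rho <= 1.0 + pert).astype(np.uint8)

    vol = np.full(spec.shape, spec.background, dtype=np.float32)
    if spec.texture_scale > 0:
        tex = ndimage.gaussian_filter(rng.normal(size=spec.shape), sigma=3.0)
        tex /= max(float(np.abs(tex).max()), 1e-9)
        vol += spec.texture_scale * tex.astype(np.float32)

    body = mask.astype(np.float32)
    if spec.cylinder_radius_mm > 0:
        d = np.asarray(spec.cylinder_direction, float)
        d /= np.linalg.norm(d)
        proj = grid @ d
        radial = grid - proj[..., None] * d
        dist = np.linalg.norm(radial, axis=-1)
        body = np.maximum(body, (dist <= spec.cylinder_radius_mm).astype(np.float32))
    body = ndimage.gaussian_filter(body, sigma=0.6)
    vol += spec.contrast * body
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    ct = CTVolume(vol.astype(np.float32), spec.spacing, window_center=0.5, window_width=1.0)
    return ct, MaskVolume(mask, spec.spacing)


def _crop_truth(truth: np.ndarray, ref: PatchRef) -> np.ndarray:
    r0, r1 = ref.rows
    c0, c1 = ref.cols
    i = ref.index
    nz, ny, nx = truth.shape
    if ref.view == "axial":
        if not (0 <= i < nz and 0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
            raise IndexError(f"axial patch {ref} outside volume {truth.shape}")
        return truth[i, r0:r1, c0:c1]
    if ref.view == "coronal":  # rows = x, cols = z, fixed y
        if not (0 <= i < ny and 0 <= r0 < r1 <= nx and 0 <= c0 < c1 <= nz):
            raise IndexError(f"coronal patch {ref} outside volume {truth.shape}")
        return truth[c0:c1, i, r0:r1].T
    if ref.view == "sagittal":  # rows = y, cols = z, fixed x
        if not (0 <= i < nx and 0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nz):
            raise IndexError(f"sagittal patch {ref} outside volume {truth.shape}")
        return truth[c0:c1, r0:r1, i].T
    raise ValueError(f"unknown view {ref.view!r}")


def oracle_segmenter(
    truth: MaskVolume,
    error_model: str = "none",
    p: float = 0.3,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> Segmenter:
    """Segmenter test double backed by the ground truth.

    ``error_model``:

    * ``"none"`` — exact truth crop;
    * ``"dilate_p"`` / ``"erode_p"`` — with probability ``p`` per patch,
      dilate / erode the cropped truth by one pixel;
    * ``"noisy"`` — with probability ``p`` per patch, erode or dilate by
      one pixel (equal odds);
    * ``"flip"`` — flip each pixel independently with rate ``flip_rate``.

    Corruption is deterministic per ``seed`` *and* patch location, so
    repeated calls for the same patch agree regardless of call order.
    """
    data = truth.data

    def segment(patch: np.ndarray, ref: PatchRef) -> np.ndarray:
        crop = _crop_truth(data, ref).astype(np.uint8)
        if crop.shape != patch.shape:
            raise IndexError(f"patch shape {patch.shape} != truth crop {crop.shape}")
        if error_model == "none":
            return crop.copy()
        rng = np.random.default_rng(
            [seed, _VIEW_CODE[ref.view], ref.index, ref.rows[0], ref.cols[0]]
        )
        out = crop.copy()
        if error_model in ("dilate_p", "erode_p", "noisy"):
            if rng.random() < p:
                if error_model == "noisy":
                    op = "dilate" if rng.random() < 0.5 else "erode"
                else:
                    op = "dilate" if error_model == "dilate_p" else "erode"
                if op == "dilate":
                    out = ndimage.binary_dilation(out).astype(np.uint8)
                else:
                    out = ndimage.binary_erosion(out).astype(np.uint8)
        elif error_model == "flip":
            flips = rng.random(out.shape) < flip_rate
            out = np.where(flips, 1 - out, out).astype(np.uint8)
        else:
            raise ValueError(f"unknown error model {error_model!r}")
        return out

    return segment


@dataclass
class ROISample:
    """One training sample: an image patch, its mask crop and provenance."""

    patch: np.ndarray
    mask: np.ndarray
    roi: SquareROI
    margins: tuple[int, int, int, int]
    is_nodule: bool


def _square_up(x1, x2, y1, y2, ny, nx):
    """Grow the short side (extra voxel to the high-index side), clamp."""
    w, h = x2 - x1, y2 - y1
    if w < h:
        d = h - w
        x1 -= d // 2
        x2 += d - d // 2
    elif h < w:
        d = w - h
        y1 -= d // 2
        y2 += d - d // 2
    # clamp by translation
    if x1 < 0:
        x2 -= x1
        x1 = 0
    if x2 > nx:
        x1 -= x2 - nx
        x2 = nx
    if y1 < 0:
        y2 -= y1
        y1 = 0
    if y2 > ny:
        y1 -= y2 - ny
        y2 = ny
    side = min(x2 - x1, y2 - y1)  # if the image itself is too small
    return x1, x1 + side, y1, y1 + side


def sample_training_rois(
    vol: CTVolume,
    truth: MaskVolume,
    n_per_slice: int = 4,
    include_non_nodule: int = 2,
    seed: int = 0,
) -> list[ROISample]:
    """Draw training ROIs with the random-margins strategy.

    For every nodule-bearing axial slice, each of the four margins of
    the tight in-slice bounding box is drawn uniformly from
    ``[0, D]`` where ``D`` is the in-slice maximum diameter (bounding
    box long side); the window is then squared up by expanding the short
    side. Placing the nodule anywhere inside the ROI (not just at the
    centre) is what lets a trained network report the nodule position
    that the adaptive-ROI update relies on. Additionally,
    ``include_non_nodule`` empty-mask ROIs are taken from the slices
    just beyond each end of the nodule.
    """
    if truth.data.sum() == 0:
        raise ValueError("ground truth is empty")
    rng = np.random.default_rng(seed)
    nz, ny, nx = vol.data.shape
    samples: list[ROISample] = []

    nodule_slices = np.nonzero(truth.data.any(axis=(1, 2)))[0]
    boxes = {}
    for z in nodule_slices:
        ys, xs = np.nonzero(truth.data[z])
        boxes[int(z)] = (int(xs.min()), int(xs.max()) + 1, int(ys.min()), int(ys.max()) + 1)

    for z in nodule_slices:
        bx1, bx2, by1, by2 = boxes[int(z)]
        diameter = max(bx2 - bx1, by2 - by1)
        for _ in range(n_per_slice):
            ml, mr, mt, mb = rng.integers(0, diameter + 1, size=4)
            x1, x2 = bx1 - ml, bx2 + mr
            y1, y2 = by1 - mt, by2 + mb
            x1, x2, y1, y2 = _square_up(x1, x2, y1, y2, ny, nx)
            roi = SquareROI(int(z), x1, x2, y1, y2)
            samples.append(
                ROISample(
                    patch=vol.data[z, y1:y2, x1:x2].copy(),
                    mask=truth.data[z, y1:y2, x1:x2].copy(),
                    roi=roi,
                    margins=(int(ml), int(mr), int(mt), int(mb)),
                    is_nodule=True,
                )
            )

    # non-nodule ROIs just above / below the nodule, window borrowed from
    # the nearest nodule slice's tight box
    z_lo, z_hi = int(nodule_slices.min()), int(nodule_slices.max())
    for end, direction in ((z_lo, -1), (z_hi, +1)):
        bx1, bx2, by1, by2 = boxes[end]
        x1, x2, y1, y2 = _square_up(bx1, bx2, by1, by2, ny, nx)
        for k in range(1, include_non_nodule + 1):
            z = end + direction * k
            if not (0 <= z < nz):
                break
            roi = SquareROI(int(z), x1, x2, y1, y2)
            samples.append(
                ROISample(
                    patch=vol.data[z, y1:y2, x1:x2].copy(),
                    mask=truth.data[z, y1:y2, x1:x2].copy(),
                    roi=roi,
                    margins=(0, 0, 0, 0),
                    is_nodule=False,
                )
            )
    return samples


def convex_phantom_suite(
    n: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 72, 72),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sigma: float = 0.02,
) -> list[tuple[CTVolume, MaskVolume]]:
    """Seeded suite of convex (lobulation-free) ellipsoid phantoms.

    Semi-axes are drawn from 4-9 mm and the centre is jittered, giving
    nodules whose per-slice area profile rises and falls — the regime
    the adaptive-ROI update has to track.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        semi = tuple(rng.uniform(4.0, 9.0, size=3))
        extent = np.array(shape) * np.array(spacing)
        center = tuple(extent / 2.0 + rng.uniform(-4.0, 4.0, size=3))
        spec = PhantomSpec(
            shape=shape,
            spacing=spacing,
            center_mm=center,
            semi_axes_mm=semi,
            lobulation=0.0,
            noise_sigma=noise_sigma,
            texture_scale=0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(spec))
    return out


def generate_blob_patches(
    n: int,
    shape: tuple[int, int] = (32, 32),
    seed: int = 0,
    noise_sigma: float = 0.05,
    empty_fraction: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D blob patches with masks, for tiny-scale network training.

    Returns ``(patches, masks)`` of shapes ``(n, H, W)``; patches are in
    [0, 1]-ish units (background ~0.15, blob contrast ~0.55 with noise).
    A fraction of patches is empty so the network also learns absence.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    patches = np.empty((n, h, w), dtype=np.float32)
    masks = np.zeros((n, h, w), dtype=np.uint8)
    for i in range(n):
        img = 0.15 + rng.normal(0.0, noise_sigma, size=shape).astype(np.float32)
        if rng.random() >= empty_fraction:
            cy = rng.uniform(0.25 * h, 0.75 * h)
            cx = rng.uniform(0.25 * w, 0.75 * w)
            ry = rng.uniform(0.12 * h, 0.3 * h)
            rx = rng.uniform(0.12 * w, 0.3 * w)
            ang = rng.uniform(0, np.pi)
            ca, sa = np.cos(ang), np.sin(ang)
            u = ((xx - cx) * ca + (yy - cy) * sa) / rx
            v = (-(xx - cx) * sa + (yy - cy) * ca) / ry
            m = (u * u + v * v <= 1.0).astype(np.uint8)
            masks[i] = m
            img += 0.55 * ndimage.gaussian_filter(m.astype(np.float32), 0.6)
        patches[i] = img
    return patches, masks
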