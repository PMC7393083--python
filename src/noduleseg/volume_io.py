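"""Volume and mask I/O with geometry and intensity normalization.

CT scans arrive with anisotropic voxels: the in-plane pixel spacing is
usually much finer than the slice thickness. Everything downstream works
on a grid whose slice spacing has been normalized to the in-plane pixel
spacing, and on intensities windowed into [0, 1] using the scan's
window-center / window-width (WC/WW) display tags.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based;
* boxes and ROIs are half-open ``[lo, hi)``;
* masks are ``uint8`` with values in {0, 1}.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Lung window used when a scan carries no WC/WW tags (HU).
DEFAULT_WINDOW_CENTER = -600.0
DEFAULT_WINDOW_WIDTH = 1500.0

#: Relative tolerance on inter-slice gap consistency for DICOM series.
SLICE_GAP_RTOL = 0.01


class GeometryError(ValueError):
    """Inconsistent or invalid voxel geometry."""


@dataclass
class CTVolume:
    """A 3-D CT intensity grid with physical spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities, HU or normalized.
    spacing : tuple of float
        Voxel spacing ``(sz, sy, sx)`` in millimetres.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in millimetres.
    window_center, window_width : float
        DICOM display window (HU). Used by :func:`normalize_intensity`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    window_center: float = DEFAULT_WINDOW_CENTER
    window_width: float = DEFAULT_WINDOW_WIDTH

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"volume must be rank-3 and non-empty, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MaskVolume:
    """Binary voxel mask aligned to a :class:`CTVolume` or VOI grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    #: optional per-slice propagation trace attached by stage I
    report: list | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be rank-3, got shape {self.data.shape}")
        uniq = np.unique(self.data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:5]}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _nifti_affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    sz, sy, sx = spacing
    oz, oy, ox = origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def _read_nifti(path: str) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(path)
    # nibabel stores (x, y, z); transpose into our (z, y, x) convention
    data = np.asanyarray(img.dataobj).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    aff = img.affine
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return data, spacing, origin


def _read_dicom_dir(path: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    if not files:
        raise IOError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        med = float(np.median(gaps))
        bad = np.nonzero(np.abs(gaps - med) > SLICE_GAP_RTOL * abs(med))[0]
        if bad.size:
            i = int(bad[0])
            raise GeometryError(
                f"inconsistent slice spacing: gap {gaps[i]:g} mm between slices "
                f"{i} and {i + 1} (median gap {med:g} mm)"
            )
        sz = abs(med)
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0))

    ps = slices[0].PixelSpacing  # (row, col) = (y, x)
    sy, sx = float(ps[0]), float(ps[1])

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=0)

    def _tag_scalar(ds, name, default):
        val = getattr(ds, name, None)
        if val is None:
            logger.warning("DICOM tag %s absent; using default %g", name, default)
            return default
        try:
            return float(val[0])  # multi-valued tag
        except TypeError:
            return float(val)

    wc = _tag_scalar(slices[0], "WindowCenter", DEFAULT_WINDOW_CENTER)
    ww = _tag_scalar(slices[0], "WindowWidth", DEFAULT_WINDOW_WIDTH)
    origin = (float(zs[0]), float(slices[0].ImagePositionPatient[1]), float(slices[0].ImagePositionPatient[0]))
    return CTVolume(data, (sz, sy, sx), origin, wc, ww)


def read_volume(path: str, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` is one of ``{"dicom_dir", "nifti"}``; when omitted it is
    inferred from the path (directory -> DICOM series).
    """
    if format is None:
        format = "dicom_dir" if os.path.isdir(path) else "nifti"
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    if format == "nifti":
        data, spacing, origin = _read_nifti(path)
        return CTVolume(data.astype(np.float32), spacing, origin)
    raise ValueError(f"unknown format {format!r}")


def write_volume(vol: CTVolume, path: str) -> None:
    """Write a volume as float32 NIfTI-1 (spacing in the header)."""
    img = nib.Nifti1Image(vol.data.T.astype(np.float32), _nifti_affine(vol.spacing, vol.origin))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, path)


def read_mask(path: str) -> MaskVolume:
    """Read a binary mask NIfTI written by :func:`write_mask`."""
    data, spacing, _ = _read_nifti(path)
    return MaskVolume((np.asarray(data) > 0).astype(np.uint8), spacing)


def write_mask(mask: MaskVolume, path: str) -> None:
    """Write a mask as uint8 NIfTI-1 with values in {0, 1}."""
    img = nib.Nifti1Image(mask.data.T.astype(np.uint8), _nifti_affine(mask.spacing, (0, 0, 0)))
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, path)


def _resample_z(data: np.ndarray, new_nz: int, order: int) -> np.ndarray:
    nz = data.shape[0]
    if new_nz == nz:
        return data.copy()
    # voxel-centre-aligned mapping: new slice j sits at the same physical z
    # as old fractional index (j + 0.5) * nz / new_nz - 0.5
    zc = (np.arange(new_nz) + 0.5) * (nz / new_nz) - 0.5
    coords = np.meshgrid(zc, np.arange(data.shape[1]), np.arange(data.shape[2]), indexing="ij")
    return ndimage.map_coordinates(data.astype(np.float32), coords, order=order, mode="nearest")


def resample_z_to_pixel_spacing(vol: CTVolume, masks: list[MaskVolume] | None = None):
    """Normalize the slice thickness to the in-plane pixel spacing.

    The z axis is linearly interpolated so that the output slice spacing
    equals ``sy`` (= ``sx``); the in-plane grid is untouched. Companion
    masks, if given, are resampled on the same grid with nearest-neighbour
    interpolation so they stay binary.

    Returns the resampled volume, or ``(volume, masks)`` when companion
    masks were supplied.
    """
    sz, sy, sx = vol.spacing
    if abs(sy - sx) > 1e-3 * max(sy, sx):
        raise GeometryError(f"in-plane spacing must be isotropic, got sy={sy}, sx={sx}")
    nz = vol.data.shape[0]
    new_nz = max(1, int(round(nz * sz / sy)))
    new_spacing = (sy, sy, sx)
    out = CTVolume(
        _resample_z(vol.data, new_nz, order=1),
        new_spacing,
        vol.origin,
        vol.window_center,
        vol.window_width,
    )
    if masks is None:
        return out
    res_masks = [
        MaskVolume(_resample_z(m.data, new_nz, order=0).astype(np.uint8), new_spacing)
        for m in masks
    ]
    return out, res_masks


def normalize_intensity(vol: CTVolume) -> CTVolume:
    """Window the intensities into [0, 1] using WC/WW.

    With ``Min = WC - WW/2`` and ``Max = WC + WW/2``, intensities are
    clipped to ``[Min, Max]`` and affinely mapped so Min -> 0, Max -> 1.
    """
    if vol.window_width <= 0:
        raise ValueError(f"window width must be > 0, got {vol.window_width}")
    lo = vol.window_center - vol.window_width / 2.0
    hi = vol.window_center + vol.window_width / 2.0
    data = (np.clip(vol.data, lo, hi) - lo) / (hi - lo)
    return replace(vol, data=data.astype(np.float32))
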