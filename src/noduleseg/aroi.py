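"""Adaptive-ROI (A-ROI) axial slice propagation — stage I.

A radiologist supplies one square ROI on one axial slice. The algorithm
segments that patch, then sweeps outward slice-by-slice in both z
directions. Between slices the ROI is (a) *recentered* so it stays
concentric with the previous slice's predicted nodule mask, and
(b) *resized* so that the nodule-area / ROI-area ratio stays at or below
a threshold ``R_T`` — a smaller ``R_T`` means a looser ROI, giving the
nodule room to drift between slices (the required slack grows with slice
thickness). A sweep stops after a configurable number of consecutive
empty predictions, i.e. immediately after the end of the nodule.

The per-slice segmenter is an opaque callable (:data:`Segmenter`), so
the geometric logic here can be driven by a trained network or by an
oracle test double interchangeably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

from .volume_io import CTVolume, MaskVolume

#: Contract for per-patch segmentation backends: maps a 2-D patch (and a
#: :class:`PatchRef` saying where it came from) to a binary mask of the
#: patch's own shape.
Segmenter = Callable[[np.ndarray, "PatchRef"], np.ndarray]


@dataclass(frozen=True)
class PatchRef:
    """Location of a 2-D patch within the parent volume.

    ``rows``/``cols`` are absolute half-open index ranges along the
    patch's height/width axes. Which volume axes those are depends on
    the view: axial -> (y, x); coronal -> (x, z); sagittal -> (y, z).
    ``index`` is the fixed coordinate along the sweep axis.
    """

    view: Literal["axial", "coronal", "sagittal"]
    index: int
    rows: tuple[int, int]
    cols: tuple[int, int]


@dataclass(frozen=True)
class SquareROI:
    """Axis-aligned square window on one axial slice, half-open."""

    slice_index: int
    x1: int
    x2: int
    y1: int
    y2: int

    def __post_init__(self) -> None:
        if self.x2 - self.x1 != self.y2 - self.y1 or self.x2 <= self.x1:
            raise ValueError(
                f"ROI must be square with positive side, got x[{self.x1},{self.x2}) y[{self.y1},{self.y2})"
            )

    @property
    def side(self) -> int:
        return self.x2 - self.x1

    @property
    def area(self) -> int:
        return self.side * self.side


@dataclass(frozen=True)
class MaskMargins:
    """Distances from the predicted mask to the four ROI edges (voxels)."""

    d_left: int
    d_right: int
    d_top: int
    d_bottom: int


@dataclass(frozen=True)
class VOIBox:
    """Integer voxel bounding box, half-open on all axes."""

    z1: int
    z2: int
    y1: int
    y2: int
    x1: int
    x2: int

    def __post_init__(self) -> None:
        if self.z2 <= self.z1 or self.y2 <= self.y1 or self.x2 <= self.x1:
            raise ValueError(f"empty VOI box {self}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.z2 - self.z1, self.y2 - self.y1, self.x2 - self.x1)


@dataclass(frozen=True)
class AROIConfig:
    """Tunables of the adaptive-ROI sweep.

    ``ratio_threshold`` is the upper bound R_T on nodule-area/ROI-area;
    the operating point is 0.6. ``resize_mode="always"`` lets the ROI
    shrink as well as grow; ``"grow_only"`` only ever enlarges it.
    ``stop_on_empty`` consecutive empty predictions end a sweep.
    """

    ratio_threshold: float = 0.6
    resize_mode: Literal["always", "grow_only"] = "always"
    min_side: int = 8
    max_steps: int = 512
    stop_on_empty: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio_threshold < 1.0:
            raise ValueError(f"ratio_threshold must lie in (0,1), got {self.ratio_threshold}")
        if self.min_side < 1 or self.max_steps < 1 or self.stop_on_empty < 1:
            raise ValueError("min_side, max_steps and stop_on_empty must all be >= 1")


class ContractViolation(RuntimeError):
    """A segmenter returned an output violating the patch contract."""


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def compute_margins(mask_2d: np.ndarray, roi: SquareROI) -> MaskMargins | None:
    """Margins between the predicted mask and the ROI edges.

    ``mask_2d`` is in ROI-local coordinates (shape side x side, indexed
    (y, x)). Returns ``None`` for an empty mask — the signal that drives
    sweep stopping, distinct from an error.
    """
    mask_2d = np.asarray(mask_2d)
    if mask_2d.shape != (roi.side, roi.side):
        raise ContractViolation(f"mask shape {mask_2d.shape} != ROI side {roi.side}")
    ys, xs = np.nonzero(mask_2d)
    if ys.size == 0:
        return None
    side = roi.side
    return MaskMargins(
        d_left=int(xs.min()),
        d_right=int(side - 1 - xs.max()),
        d_top=int(ys.min()),
        d_bottom=int(side - 1 - ys.max()),
    )


def _clamp_by_translation(x1: int, x2: int, y1: int, y2: int, extent: tuple[int, int]):
    """Slide a window fully inside ``extent`` = (ny, nx), never shrinking."""
    ny, nx = extent
    if x2 - x1 > nx or y2 - y1 > ny:
        raise ValueError(f"ROI side {x2 - x1} exceeds image extent {extent}")
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
    return x1, x2, y1, y2


def recenter(roi: SquareROI, m: MaskMargins, image_extent: tuple[int, int]) -> SquareROI:
    """Shift the ROI so it becomes concentric with the predicted mask.

    The shift along x is ``round((d_left - d_right)/2)`` (half away from
    zero) and analogously along y; the side never changes. The result is
    clamped inside the image by translation only.
    """
    shift_x = _round_half_away((m.d_left - m.d_right) / 2.0)
    shift_y = _round_half_away((m.d_top - m.d_bottom) / 2.0)
    x1, x2 = roi.x1 + shift_x, roi.x2 + shift_x
    y1, y2 = roi.y1 + shift_y, roi.y2 + shift_y
    x1, x2, y1, y2 = _clamp_by_translation(x1, x2, y1, y2, image_extent)
    return replace(roi, x1=x1, x2=x2, y1=y1, y2=y2)


def resize(
    roi: SquareROI,
    nodule_area: int,
    cfg: AROIConfig,
    image_extent: tuple[int, int],
) -> SquareROI:
    """Resize the ROI so the area ratio A_N / A_ROI stays <= R_T.

    The required area is ``A_N / R_T`` and the new side is
    ``ceil(sqrt(A_N / R_T))``, clamped below by ``cfg.min_side`` and
    above by the image extent. Growth and shrinkage are symmetric about
    the ROI centre; when the parity changes the extra voxel goes to the
    high-index side. In ``grow_only`` mode the side never decreases.
    """
    if nodule_area <= 0:
        return None  # empty-mask signal
    ny, nx = image_extent
    new_side = math.ceil(math.sqrt(nodule_area / cfg.ratio_threshold))
    new_side = max(new_side, cfg.min_side)
    new_side = min(new_side, ny, nx)
    if cfg.resize_mode == "grow_only":
        new_side = max(new_side, roi.side)
    delta = new_side - roi.side
    if delta == 0:
        return roi
    a = abs(delta) // 2
    b = abs(delta) - a  # bias to the high-index side
    if delta > 0:
        x1, x2, y1, y2 = roi.x1 - a, roi.x2 + b, roi.y1 - a, roi.y2 + b
    else:
        x1, x2, y1, y2 = roi.x1 + a, roi.x2 - b, roi.y1 + a, roi.y2 - b
    x1, x2, y1, y2 = _clamp_by_translation(x1, x2, y1, y2, image_extent)
    return replace(roi, x1=x1, x2=x2, y1=y1, y2=y2)


def _segment_patch(vol: CTVolume, roi: SquareROI, z: int, segmenter: Segmenter) -> np.ndarray:
    patch = vol.data[z, roi.y1 : roi.y2, roi.x1 : roi.x2]
    ref = PatchRef("axial", z, (roi.y1, roi.y2), (roi.x1, roi.x2))
    pred = np.asarray(segmenter(patch, ref))
    if pred.shape != patch.shape:
        raise ContractViolation(
            f"segmenter returned shape {pred.shape} for patch shape {patch.shape}"
        )
    return (pred > 0).astype(np.uint8)


def propagate_axial(
    vol: CTVolume,
    seed_roi: SquareROI,
    segmenter: Segmenter,
    cfg: AROIConfig = AROIConfig(),
) -> MaskVolume:
    """Sweep the adaptive ROI through the axial slices.

    The seed slice is segmented with the ROI exactly as given; then two
    independent sweeps run toward increasing and decreasing z. At each
    step the ROI is recentered and resized from the previous slice's
    prediction, the next slice's patch is segmented, and the mask is
    written back into volume coordinates. A sweep ends at the volume
    boundary, after ``cfg.max_steps`` steps, or after
    ``cfg.stop_on_empty`` consecutive empty predictions.

    Returns the union mask volume; its ``report`` attribute carries one
    record per visited slice with the ROI used, the predicted nodule
    area and the area ratio.
    """
    nz, ny, nx = vol.data.shape
    out = np.zeros(vol.data.shape, dtype=np.uint8)
    records: list[dict] = []

    z0 = seed_roi.slice_index
    if not (0 <= z0 < nz):
        raise ValueError(f"seed slice {z0} outside volume with {nz} slices")

    seed_pred = _segment_patch(vol, seed_roi, z0, segmenter)
    records.append(_record(z0, seed_roi, seed_pred))
    if seed_pred.sum() == 0:
        return MaskVolume(out, vol.spacing, report=records)
    out[z0, seed_roi.y1 : seed_roi.y2, seed_roi.x1 : seed_roi.x2] |= seed_pred

    for direction in (+1, -1):
        roi = replace(seed_roi)
        prev = seed_pred
        z = z0
        empties = 0
        for _ in range(cfg.max_steps):
            margins = compute_margins(prev, roi)
            if margins is not None:
                roi = recenter(roi, margins, (ny, nx))
                resized = resize(roi, int(prev.sum()), cfg, (ny, nx))
                if resized is not None:
                    roi = resized
            z += direction
            if not (0 <= z < nz):
                break
            roi = replace(roi, slice_index=z)
            pred = _segment_patch(vol, roi, z, segmenter)
            records.append(_record(z, roi, pred))
            if pred.sum() == 0:
                empties += 1
                if empties >= cfg.stop_on_empty:
                    break
            else:
                empties = 0
                out[z, roi.y1 : roi.y2, roi.x1 : roi.x2] |= pred
            prev = pred

    records.sort(key=lambda r: r["z"])
    return MaskVolume(out, vol.spacing, report=records)


def _record(z: int, roi: SquareROI, pred: np.ndarray) -> dict:
    area = int(pred.sum())
    return {
        "z": int(z),
        "roi": {"x1": roi.x1, "x2": roi.x2, "y1": roi.y1, "y2": roi.y2, "side": roi.side},
        "nodule_area": area,
        "ratio": area / roi.area,
    }


def extract_voi(stage1_mask: MaskVolume, pad: int = 2) -> VOIBox | None:
    """Tight bounding box of the stage-I mask, padded and clipped.

    Returns ``None`` for an empty mask (the no-nodule signal).
    """
    idx = np.argwhere(stage1_mask.data)
    if idx.size == 0:
        return None
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, stage1_mask.data.shape)
    return VOIBox(int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]), int(lo[2]), int(hi[2]))
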