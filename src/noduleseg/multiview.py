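"""Stage II: coronal / sagittal patch-wise investigation of the VOI.

The VOI found by stage I is re-sliced along the other two anatomical
axes and every cross-section is segmented independently. Because the
z axis is the coarse one before slice-thickness normalization, the
networks for these views work at 128 (in-plane) x 64 (z); the resizing
to and from that resolution lives inside the segmenter, so the oracle
test double and a trained model are interchangeable here too.

Patch layout: a coronal patch (fixed y) is (x, z)-indexed, a sagittal
patch (fixed x) is (y, z)-indexed — in-plane axis first (height), z
second (width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aroi import ContractViolation, PatchRef, Segmenter, VOIBox
from .volume_io import CTVolume, MaskVolume


@dataclass
class ViewStack:
    """Ordered cross-sections of a VOI along one sweep axis."""

    view: str  # "coronal" (sweep y) or "sagittal" (sweep x)
    patches: list[np.ndarray]
    refs: list[PatchRef]
    voi: VOIBox
    spacing: tuple[float, float, float]


def extract_view_stack(vol: CTVolume, voi: VOIBox, view: str) -> ViewStack:
    """Slice the VOI into per-index coronal or sagittal patches."""
    z1, z2, y1, y2, x1, x2 = voi.z1, voi.z2, voi.y1, voi.y2, voi.x1, voi.x2
    nz, ny, nx = vol.data.shape
    if not (0 <= z1 < z2 <= nz and 0 <= y1 < y2 <= ny and 0 <= x1 < x2 <= nx):
        raise ValueError(f"VOI {voi} not contained in volume {vol.data.shape}")
    patches, refs = [], []
    if view == "coronal":
        for y in range(y1, y2):
            patches.append(vol.data[z1:z2, y, x1:x2].T.copy())  # (x, z)
            refs.append(PatchRef("coronal", y, (x1, x2), (z1, z2)))
    elif view == "sagittal":
        for x in range(x1, x2):
            patches.append(vol.data[z1:z2, y1:y2, x].T.copy())  # (y, z)
            refs.append(PatchRef("sagittal", x, (y1, y2), (z1, z2)))
    else:
        raise ValueError(f"view must be 'coronal' or 'sagittal', got {view!r}")
    return ViewStack(view, patches, refs, voi, vol.spacing)


def segment_view(stack: ViewStack, segmenter: Segmenter) -> MaskVolume:
    """Segment every patch of the stack and assemble a VOI-aligned mask."""
    dz, dy, dx = stack.voi.shape
    out = np.zeros((dz, dy, dx), dtype=np.uint8)
    for patch, ref in zip(stack.patches, stack.refs):
        pred = np.asarray(segmenter(patch, ref))
        if pred.shape != patch.shape:
            raise ContractViolation(
                f"segmenter returned {pred.shape} for patch {patch.shape} ({ref})"
            )
        pred = (pred > 0).astype(np.uint8)
        if stack.view == "coronal":
            out[:, ref.index - stack.voi.y1, :] = pred.T  # (x, z) -> (z, x)
        else:
            out[:, :, ref.index - stack.voi.x1] = pred.T  # (y, z) -> (z, y)
    return MaskVolume(out, stack.spacing)
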