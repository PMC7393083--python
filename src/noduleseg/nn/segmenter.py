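"""Adapter exposing a trained network through the patch-segmenter contract.

The geometric pipeline hands over patches of whatever size the adaptive
ROI currently has; the network wants its fixed input resolution. The
adapter resizes the patch up (bilinear), runs the forward pass,
thresholds the probabilities, and resizes the binary mask back to the
patch's original shape with nearest-neighbour interpolation so it stays
binary.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as sk_resize

from ..aroi import PatchRef, Segmenter
from .resunet import ResUNet


def as_segmenter(model: ResUNet, threshold: float = 0.5) -> Segmenter:
    """Wrap a trained model as a ``(patch, ref) -> binary mask`` callable."""
    target = model.spec.input_shape

    def segment(patch: np.ndarray, ref: PatchRef | None = None) -> np.ndarray:
        patch = np.asarray(patch, dtype=np.float32)
        if patch.shape == target:
            x = patch
        else:
            x = sk_resize(patch, target, order=1, preserve_range=True, anti_aliasing=False)
        prob = model.forward(x[None, ..., None].astype(np.float32), train=False)[0, ..., 0]
        mask = prob >= threshold
        if mask.shape != patch.shape:
            mask = (
                sk_resize(mask.astype(np.float32), patch.shape, order=0, preserve_range=True,
                          anti_aliasing=False)
                > 0.5
            )
        return mask.astype(np.uint8)

    return segment
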