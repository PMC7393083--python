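"""Voxel-majority consensus fusion of aligned binary masks.

Given M aligned estimates, a voxel enters the fused mask when its vote
count g satisfies g >= M * C_R, where C_R is the consensus ratio. With
the default C_R = 0.5 this is a 50% consensus: 2-of-3 for the three
view masks (axial, coronal, sagittal), and 2-of-4 for the four-rater
ground-truth construction used with LIDC-style annotations — the same
rule serves both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import MaskVolume


@dataclass(frozen=True)
class ConsensusConfig:
    consensus_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.consensus_ratio <= 1.0:
            raise ValueError(f"consensus_ratio must lie in (0,1], got {self.consensus_ratio}")


def consensus(masks: list[MaskVolume], cfg: ConsensusConfig = ConsensusConfig()) -> MaskVolume:
    """Fuse M aligned masks by thresholded voting (g >= M * C_R)."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].data.shape
    spacing = masks[0].spacing
    for m in masks[1:]:
        if m.data.shape != shape:
            raise ValueError(f"shape mismatch: {m.data.shape} vs {shape}")
        if not np.allclose(m.spacing, spacing):
            raise ValueError(f"spacing mismatch: {m.spacing} vs {spacing}")
    votes = np.zeros(shape, dtype=np.int32)
    for m in masks:
        votes += m.data
    fused = (votes >= len(masks) * cfg.consensus_ratio).astype(np.uint8)
    return MaskVolume(fused, spacing)
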