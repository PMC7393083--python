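"""Segmentation evaluation: Dice, sensitivity, PPV, Hausdorff distance.

All overlap metrics treat masks as voxel sets. The Hausdorff distance is
computed on foreground voxel centres scaled by the physical spacing, so
it is reported in millimetres. Conventions for degenerate inputs:
two empty masks agree perfectly (DSC = SEN = PPV = 1); a Hausdorff
distance involving an empty mask is undefined and reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .volume_io import MaskVolume


@dataclass
class EvalReport:
    dsc: float
    sen: float
    ppv: float
    hd_mm: float | None
    tp: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "sen": self.sen,
            "ppv": self.ppv,
            "hd_mm": self.hd_mm,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def _check(pred: MaskVolume, ref: MaskVolume) -> None:
    if pred.data.shape != ref.data.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs ref {ref.data.shape}")


def dsc(pred: MaskVolume, ref: MaskVolume) -> float:
    """Dice similarity coefficient 2|P∩R| / (|P| + |R|), in [0, 1]."""
    _check(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / denom


def sen_ppv(pred: MaskVolume, ref: MaskVolume) -> tuple[float, float]:
    """Sensitivity |P∩R|/|R| and positive predictive value |P∩R|/|P|.

    A zero denominator (nothing to detect / nothing predicted) yields
    1.0 for that ratio — vacuous agreement.
    """
    _check(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)
    inter = int((p & r).sum())
    np_, nr = int(p.sum()), int(r.sum())
    sen = inter / nr if nr else 1.0
    ppv = inter / np_ if np_ else 1.0
    return sen, ppv


def _points_mm(mask: MaskVolume) -> np.ndarray:
    return np.argwhere(mask.data).astype(float) * np.asarray(mask.spacing)


def directed_hausdorff_mm(a: MaskVolume, b: MaskVolume) -> float | None:
    """Directed Hausdorff distance H(A, B) = max_a min_b ||a-b||, mm."""
    _check(a, b)
    pa, pb = _points_mm(a), _points_mm(b)
    if pa.size == 0 or pb.size == 0:
        return None
    return float(directed_hausdorff(pa, pb)[0])


def hausdorff_mm(pred: MaskVolume, ref: MaskVolume) -> float | None:
    """Symmetric Hausdorff distance max(H(P,R), H(R,P)) in millimetres.

    ``None`` when either mask is empty (undefined, not zero).
    """
    _check(pred, ref)
    pa, pb = _points_mm(pred), _points_mm(ref)
    if pa.size == 0 or pb.size == 0:
        return None
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))


def evaluate(pred: MaskVolume, ref: MaskVolume) -> EvalReport:
    """Full report: DSC, SEN, PPV, Hausdorff (mm) and voxel counts."""
    _check(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    fn = int((~p & r).sum())
    s, v = sen_ppv(pred, ref)
    return EvalReport(
        dsc=dsc(pred, ref), sen=s, ppv=v, hd_mm=hausdorff_mm(pred, ref), tp=tp, fp=fp, fn=fn
    )
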