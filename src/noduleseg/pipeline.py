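"""End-to-end pipeline: preprocess -> stage I -> VOI -> stage II -> consensus.

``segment_volume`` drives the full two-stage method from one seed ROI
and three per-view segmenters, and optionally scores every stage
against a reference mask. ``rt_sweep`` reruns the pipeline over a
phantom suite for a grid of area-ratio thresholds R_T, the sensitivity
harness for picking the operating point. The rater-consensus ground
truth construction (50% consensus over up to four rater masks, nodules
under 3 mm excluded) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aroi import AROIConfig, SquareROI, Segmenter, VOIBox, extract_voi, propagate_axial
from .consensus import ConsensusConfig, consensus
from .metrics import dsc
from .multiview import extract_view_stack, segment_view
from .volume_io import CTVolume, MaskVolume


@dataclass
class PipelineConfig:
    """Operating parameters of the two-stage method.

    Defaults are the method's operating point: area-ratio threshold
    R_T = 0.6 and consensus ratio C_R = 0.5.
    """

    ratio_threshold: float = 0.6
    consensus_ratio: float = 0.5
    voi_pad: int = 2
    min_side: int = 8
    max_steps: int = 512
    stop_on_empty: int = 1
    resize_mode: str = "always"
    binarize_threshold: float = 0.5
    seed: int = 0

    def aroi(self) -> AROIConfig:
        return AROIConfig(
            ratio_threshold=self.ratio_threshold,
            resize_mode=self.resize_mode,
            min_side=self.min_side,
            max_steps=self.max_steps,
            stop_on_empty=self.stop_on_empty,
        )


@dataclass
class PipelineResult:
    status: str  # "ok" | "no_nodule"
    mask: MaskVolume | None = None  # final consensus mask, full-volume grid
    voi: VOIBox | None = None
    stage_masks: dict = field(default_factory=dict)  # VOI-aligned per-stage masks
    report: dict = field(default_factory=dict)


def _crop(mask: MaskVolume, voi: VOIBox) -> MaskVolume:
    sub = mask.data[voi.z1 : voi.z2, voi.y1 : voi.y2, voi.x1 : voi.x2]
    return MaskVolume(sub.copy(), mask.spacing)


def _embed(mask: MaskVolume, voi: VOIBox, full_shape: tuple[int, int, int]) -> MaskVolume:
    out = np.zeros(full_shape, dtype=np.uint8)
    out[voi.z1 : voi.z2, voi.y1 : voi.y2, voi.x1 : voi.x2] = mask.data
    return MaskVolume(out, mask.spacing)


def segment_volume(
    vol: CTVolume,
    seed_roi: SquareROI,
    segmenters: dict[str, Segmenter],
    config: PipelineConfig = PipelineConfig(),
    reference: MaskVolume | None = None,
) -> PipelineResult:
    """Run both stages and the consensus fusion from one seed ROI.

    ``segmenters`` maps ``"axial"``, ``"coronal"`` and ``"sagittal"``
    to patch segmenters. When ``reference`` is given the report carries
    a DSC per stage (axial, coronal, sagittal, consensus), all measured
    inside the VOI, plus the A-ROI per-slice trace.
    """
    for key in ("axial", "coronal", "sagittal"):
        if key not in segmenters:
            raise ValueError(f"missing segmenter for view {key!r}")

    stage1 = propagate_axial(vol, seed_roi, segmenters["axial"], config.aroi())
    voi = extract_voi(stage1, pad=config.voi_pad)
    if voi is None:
        return PipelineResult(status="no_nodule", report={"aroi_trace": stage1.report})

    axial_voi = _crop(stage1, voi)
    coronal = segment_view(extract_view_stack(vol, voi, "coronal"), segmenters["coronal"])
    sagittal = segment_view(extract_view_stack(vol, voi, "sagittal"), segmenters["sagittal"])
    fused = consensus(
        [axial_voi, coronal, sagittal], ConsensusConfig(config.consensus_ratio)
    )

    stage_masks = {
        "axial": axial_voi,
        "coronal": coronal,
        "sagittal": sagittal,
        "consensus": fused,
    }
    report: dict = {
        "aroi_trace": stage1.report,
        "voi": {"z": [voi.z1, voi.z2], "y": [voi.y1, voi.y2], "x": [voi.x1, voi.x2]},
    }
    if reference is not None:
        ref_voi = _crop(reference, voi)
        report["dsc"] = {name: dsc(m, ref_voi) for name, m in stage_masks.items()}
    return PipelineResult(
        status="ok",
        mask=_embed(fused, voi, vol.data.shape),
        voi=voi,
        stage_masks=stage_masks,
        report=report,
    )


def seed_roi_from_truth(truth: MaskVolume, margin: int = 3) -> SquareROI:
    """Seed ROI a user would plausibly draw: the truth's largest-area
    axial slice, tight box plus a margin, squared up."""
    areas = truth.data.sum(axis=(1, 2))
    z = int(np.argmax(areas))
    ys, xs = np.nonzero(truth.data[z])
    x1, x2 = int(xs.min()) - margin, int(xs.max()) + 1 + margin
    y1, y2 = int(ys.min()) - margin, int(ys.max()) + 1 + margin
    side = max(x2 - x1, y2 - y1)
    cx, cy = (x1 + x2) // 2, (y1 + y2) // 2
    x1, y1 = cx - side // 2, cy - side // 2
    nz, ny, nx = truth.data.shape
    x1 = min(max(x1, 0), nx - side)
    y1 = min(max(y1, 0), ny - side)
    return SquareROI(z, x1, x1 + side, y1, y1 + side)


def rt_sweep(
    cases: list[tuple[CTVolume, MaskVolume, dict[str, Segmenter]]],
    rt_grid: list[float],
    config: PipelineConfig = PipelineConfig(),
) -> list[dict]:
    """Mean +/- sd consensus DSC per R_T over a case suite.

    Each case supplies a volume, its ground truth (used both for the
    seed ROI and for scoring) and per-view segmenters. Returns one row
    per R_T value: ``{"rt", "mean_dsc", "sd_dsc", "n"}``.
    """
    rows = []
    for rt in rt_grid:
        if not 0.0 < rt < 1.0:
            raise ValueError(f"R_T grid values must lie in (0,1), got {rt}")
        scores = []
        for vol, truth, segmenters in cases:
            cfg = PipelineConfig(**{**config.__dict__, "ratio_threshold": rt})
            res = segment_volume(vol, seed_roi_from_truth(truth), segmenters, cfg, reference=truth)
            scores.append(res.report["dsc"]["consensus"] if res.status == "ok" else 0.0)
        rows.append(
            {
                "rt": rt,
                "mean_dsc": float(np.mean(scores)),
                "sd_dsc": float(np.std(scores)),
                "n": len(scores),
            }
        )
    return rows


# -- rater-consensus ground truth ------------------------------------------

def nodule_max_diameter_mm(mask: MaskVolume) -> float:
    """In-plane maximum diameter: the largest axial bounding-box side, mm."""
    best = 0.0
    _, sy, sx = mask.spacing
    for z in np.nonzero(mask.data.any(axis=(1, 2)))[0]:
        ys, xs = np.nonzero(mask.data[z])
        best = max(best, (xs.max() - xs.min() + 1) * sx, (ys.max() - ys.min() + 1) * sy)
    return float(best)


def rater_consensus_ground_truth(
    rater_masks: list[MaskVolume],
    consensus_ratio: float = 0.5,
    min_diameter_mm: float = 3.0,
) -> MaskVolume | None:
    """Fuse rater annotations into a reference mask (50% consensus).

    Mirrors the LIDC-style ground-truth construction: a voxel is
    foreground when at least ``consensus_ratio`` of the raters marked
    it (2-of-4 at the default). Nodules whose in-plane maximum diameter
    falls below ``min_diameter_mm`` are filtered out (returns ``None``).
    """
    fused = consensus(rater_masks, ConsensusConfig(consensus_ratio))
    if fused.data.sum() == 0:
        return None
    if nodule_max_diameter_mm(fused) < min_diameter_mm:
        return None
    return fused


def load_lidc_scan(scan_id: str):  # pragma: no cover - requires local LIDC data
    """Load a LIDC-IDRI scan and its rater annotations (optional path).

    Requires the ``pylidc`` package and a locally configured LIDC-IDRI
    copy; neither ships with this package.
    """
    try:
        import pylidc  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            "LIDC support needs the optional 'pylidc' package and a local "
            "LIDC-IDRI download configured via ~/.pylidcrc. Install pylidc, "
            "point it at the dataset, then call load_lidc_scan again. All "
            "core functionality works without it (see noduleseg.synthetic)."
        ) from exc
    raise NotImplementedError(
        "pylidc detected, but this build ships without the LIDC adapter body; "
        "use pylidc's to_volume()/boolean_mask() and "
        "rater_consensus_ground_truth() to assemble references."
    )
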