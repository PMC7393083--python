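"""Segment a synthetic nodule phantom end to end.

Builds a lobulated nodule phantom with exact ground truth, seeds the
pipeline with the kind of square ROI a radiologist would draw on the
nodule's widest axial slice, and runs both stages plus the consensus
fusion using the ground-truth oracle segmenter (so the run isolates the
geometric machinery from network training). Prints per-stage Dice
scores: values near 1 mean each view recovered the nodule and the fused
mask agrees with the truth.
"""

from noduleseg import PhantomSpec, generate_phantom, oracle_segmenter, segment_volume
from noduleseg.metrics import evaluate
from noduleseg.pipeline import seed_roi_from_truth

spec = PhantomSpec(
    shape=(48, 96, 96),
    spacing=(1.0, 1.0, 1.0),
    semi_axes_mm=(7.0, 9.0, 8.0),
    lobulation=0.25,
    noise_sigma=0.03,
    texture_scale=0.05,
    seed=12,
)
volume, truth = generate_phantom(spec)
print(f"phantom: {int(truth.data.sum())} foreground voxels on a {spec.shape} grid")

seed_roi = seed_roi_from_truth(truth)
print(f"seed ROI: slice z={seed_roi.slice_index}, side {seed_roi.side} voxels")

oracle = oracle_segmenter(truth)
result = segment_volume(
    volume,
    seed_roi,
    {"axial": oracle, "coronal": oracle, "sagittal": oracle},
    reference=truth,
)

print(f"status: {result.status}; VOI shape (z,y,x): {result.voi.shape}")
for stage, score in result.report["dsc"].items():
    print(f"  DSC {stage:>9}: {score:.4f}")

report = evaluate(result.mask, truth)
print(
    f"final mask vs truth: DSC {report.dsc:.4f}, SEN {report.sen:.4f}, "
    f"PPV {report.ppv:.4f}, HD {report.hd_mm:.2f} mm"
)
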