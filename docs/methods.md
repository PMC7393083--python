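# Methods

## Problem setting and model

The package segments a pulmonary nodule in a 3-D CT volume from one
user-drawn square ROI on one axial slice. The method decomposes the 3-D
problem into 2-D patch segmentations tied together by geometry:

* **Stage I** sweeps the axial slices outward from the seed. At each step
  the previous slice's predicted mask determines the next slice's ROI:
  the ROI is shifted so the mask becomes concentric
  (`shift_x = round((D_L − D_R)/2)`, analogously in y, rounding half away
  from zero) and resized so the nodule-area/ROI-area ratio stays at or
  below a threshold `R_T` (`side' = ceil(sqrt(A_N / R_T))`). The bound is
  directional slack: a nodule can drift between adjacent slices by an
  amount that grows with slice thickness, and a looser ROI (smaller
  `R_T`) gives the next prediction room to find it.
* **Stage II** takes the padded bounding box of the stage-I mask (the
  VOI), re-slices it along the coronal and sagittal axes, and segments
  each cross-section independently. Patches are oriented in-plane-first:
  a coronal patch is (x, z), a sagittal patch (y, z).
* **Consensus** fuses the three VOI-aligned masks per voxel: foreground
  iff the vote count `g ≥ M·C_R`. With `M = 3, C_R = 0.5` this is 2-of-3;
  the same operation at `M = 4` realizes the 50% rater-consensus rule used
  to build ground truth from four-rater annotations (2-of-4; the `≥`
  makes the boundary case inclusive).

Assumptions: one nodule per seed ROI; the nodule's axial support is a
contiguous slice range (the sweep stops at the first run of
`stop_on_empty` empty predictions); in-plane pixel spacing is isotropic.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ratio_threshold` (R_T) | 0.6 | upper bound on A_N/A_ROI; smaller = looser ROI |
| `consensus_ratio` (C_R) | 0.5 | fraction of sources needed per voxel |
| `resize_mode` | `always` | ROI side may also shrink; `grow_only` never shrinks |
| `min_side` | 8 voxels | floor on the ROI side; guards against tiny patches being upscaled to 128 and destroyed by interpolation |
| `voi_pad` | 2 voxels | margin added to the stage-I bounding box |
| `stop_on_empty` | 1 | consecutive empty slices that end a sweep (2 tolerates interpolation gaps in thin nodules) |
| `binarize_threshold` | 0.5 | probability cut for network outputs |
| window WC/WW | −600 / 1500 HU | fallback lung window when DICOM tags are absent (logged) |

The enforced ratio invariant is `A_N/A_ROI ≤ R_T`: enlargement triggers
when the ratio exceeds `R_T`, and `A_ROI ≥ A_N` implies `R_T ∈ (0, 1)`.
Within a propagation step the order is recenter → resize; both are
deterministic, so identical inputs reproduce identical ROI sequences.

## Networks and training

Per-slice segmentation uses residual U-Nets of pre-activation units
(BN → ReLU → 3×3 conv, twice; stride 2 on the first conv of a
downsampling unit; identity shortcut, realized as a 1×1 stride-matched
projection when the shape changes — the standard residual practice).
Decoder units are preceded by 2× nearest-neighbour upsampling and
concatenation of the matching encoder map; a final 1×1 conv + sigmoid
emits probabilities. The axial spec is 9 levels / 19 conv layers at
128×128 (bridge 8×8×1024); the coronal/sagittal spec is 7 levels /
15 conv layers at 128×64 (bridge 16×8×512) — the narrower z axis of
those views motivates the 128×64 patch size. Shortcut projections are
bookkept separately from the 19/15 unit convolutions.

The loss is the mean soft-Dice complement with ε = 1e−7 in the
denominator (finite on empty masks); its denominator is the mask-sum
|P|+|T|, which keeps the loss in [0, 1] and makes it exactly 1 − DSC on
binary predictions. The optimizer is SGD (optional classical momentum);
the full-scale reference configuration is learning rate 1e−4, batch 8,
up to 700 epochs. Everything — forward, backward, batch-norm statistics,
the optimizer — is implemented in numpy (`noduleseg.nn`), channels-last
float32, convolution via im2col; gradients are verified against central
finite differences in the test suite. Training ROIs use the
random-margins strategy: each margin of the in-slice tight box is drawn
uniformly from [0, D] (D = in-slice bounding-box long side, our proxy
for the maximum in-slice diameter), so the nodule appears anywhere in
the patch, which is what lets the A-ROI update read the nodule position
from a prediction; empty patches beyond the top/bottom slices teach
absence.

Small-scale training runs (the shipped 5-level, 32×32 spec) use learning
rate 0.1 with momentum 0.9 — at this width and patch size the reference
rate would need orders of magnitude more epochs; both settings are plain
`TrainConfig` fields.

## Preprocessing

Slice thickness is normalized to the in-plane pixel spacing by linear
interpolation along z only (e.g. (2.5, 0.66, 0.66) mm → 0.66 mm
isotropic; new slice count `round(nz·sz/sy)`), with voxel-centre-aligned
sampling so constant volumes are preserved exactly and mask volumes are
preserved to discretization error. Masks are resampled nearest-neighbour
to stay binary; whether the original study interpolated or re-derived
masks after normalization is unknown, so this choice is flagged here.
Intensities are windowed to [0, 1] via `Min = WC − WW/2`,
`Max = WC + WW/2`, clip to [Min, Max], then `(I − Min)/(Max − Min)`;
clipping is required for the output to stay in [0, 1].

## Synthetic phantoms and what they show

`noduleseg.synthetic` generates radially perturbed ellipsoids (smooth
low-order angular perturbation scaled by a lobulation amplitude) on
configurable anisotropic grids, with contrast over a textured background,
Gaussian noise, and optionally an attached cylinder (juxta-vascular case;
part of the image, not the truth). The ground truth is exact by
construction. The oracle segmenter returns the truth crop for any patch,
optionally corrupted (one-pixel erode/dilate with probability p, or
pixel flips), deterministically per seed and patch location.

This emulates the geometry of the problem — per-slice area profiles that
wax and wane, inter-slice drift, multi-view consistency — but not real
CT appearance: no reconstruction physics, no fuzzy or spiculated margins,
no attached-nodule ambiguity, no inter-rater variability. Passing tests
therefore certify the geometric and fusion machinery and the learning
mechanics, not clinical-grade accuracy on patient data.

Study conditions used by the acceptance suite (chosen once, as realistic
desk-scale conditions): 20 convex phantoms with semi-axes 4–9 mm on
40×72×72 unit-spacing grids, noise σ = 0.02; noisy-oracle corruption
p = 0.3; 500 randomized slice sequences for the ROI invariants; tiny-scale
learning on 200 training / 50 held-out 32×32 blob patches, 25 epochs.
These sizes keep the whole suite to a few minutes on one CPU core.

## Numerical and design choices

* Index convention: 0-based `(z, y, x)`, half-open boxes everywhere.
* Rounding: recentering shifts round half away from zero (keeps opposing
  margins within 1); ROI side uses ceil; parity changes bias the extra
  voxel to the high-index side.
* The ROI may shrink as well as grow by default (`resize_mode="always"`,
  the side tracking `ceil(sqrt(A_N/R_T))` both ways); `grow_only`
  reproduces the enlargement-only reading of the update rule.
* The seed ROI is used exactly as given for the first segmentation.
* Empty predictions are signals (`None` margins / empty VOI), not
  exceptions; they drive sweep stopping and the "no nodule" exit path.
* Hausdorff distances use all foreground voxel centres (not surfaces),
  scaled by spacing, via the exact directed-Hausdorff routine in scipy;
  tests pin it to an O(|A||B|) brute-force double loop. An empty mask
  makes the distance undefined (reported as missing, never 0).
* Degenerate-overlap conventions: both masks empty → DSC = SEN = PPV = 1;
  a single empty denominator yields 1 for that ratio (vacuous agreement).
* DICOM series are validated for uniform slice gaps (1% of the median
  gap); violations raise a geometry error naming the offending gap.

## Limitations

* The LIDC adapter is a thin optional path: the consensus ground-truth
  construction and the ≥ 3 mm diameter filter are implemented and tested
  on synthetic rater masks, but loading real scans requires pylidc and a
  local dataset, neither bundled.
* A single fixed re-scaling resolution (128×128) distorts very small
  nodules; the spec hooks (`NetworkSpec` is resolution-parametric) allow
  training networks at 64×64/32×32/16×16, but none are shipped.
* No oblique reformats, no tri-planar fused inputs, no probabilistic
  (STAPLE-style) fusion, no longitudinal analysis.
* The in-slice "maximum diameter" used by the margin sampler is the
  bounding-box long side, a Feret-diameter proxy.
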