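# Methods

## Problem

Ascites — free fluid in the peritoneal cavity — is a key emergency
finding on abdominopelvic CT. On contrast-enhanced CT it shows
near-water attenuation (roughly −10 to +30 HU), which overlaps the
fluid inside a distended urinary bladder or a large ovarian cyst, so a
pure intensity rule cannot separate pathological free fluid from
physiological fluid-filled structures. This package trains a deep
residual U-Net to produce a per-pixel ascites probability map from a
single axial slice; the map supports three read-outs at once:
segmentation (the mask), detection (is any clinically meaningful fluid
present on this slice?), and quantification (fluid volume from mask
areas and slice geometry).

## Preprocessing

DICOM stored values are mapped to Hounsfield units through the rescale
tags (`HU = stored * RescaleSlope + RescaleIntercept`). An abdomen
display window of width 400 HU at level 60 HU is applied as

    x = clip((HU − (level − width/2)) / width, 0, 1),

i.e. [−140, 260] HU maps linearly onto [0, 1]; this is monotone in HU
and places water-range fluid near 0.35–0.43. Images are down-sampled
512 → 256 (aligned block averaging for integer factors — the exact
bilinear limit for ×2 — bilinear otherwise; up-sizing is refused).
Masks are down-sampled with nearest-neighbour sampling at pixel
centres so they stay strictly binary. The windowed grid is replicated
onto three identical channels to form the (256, 256, 3) model input;
single-slice modelling gives no natural second or third channel, and
replication keeps the first convolution's expected input scale
unchanged.

## Augmentation and balancing

Each augmented sample draws one transform — a rotation uniform in
(−10°, +10°) plus independent horizontal/vertical flips with
probability 1/2 each — and applies the *same* transform to image and
mask (bilinear for the image, bilinear + 0.5 re-binarization for the
mask; out-of-frame pixels are 0, i.e. the HU window floor). Rotation
is applied before flips; pure flips preserve mask cardinality exactly.
Class balancing keeps every original slice and fills each class to a
common target count with augmented copies drawn with replacement, so
the output class ratio is exactly 1:1. Augmented entries are
manifest-level records (source slice + draw seed); pixels are
materialized lazily, which makes cohort-scale manifests (tens of
thousands of entries) testable without rendering them.

## Architecture

The network is an encoder–bridge–decoder U-Net built from
pre-activation residual units: the main path is [BN → ReLU → conv]
repeated `convs_per_block` times (2 by default), added to a shortcut
path. The shortcut is the identity where shapes match and a 1×1
projection convolution (with the block's stride) where they do not —
the standard choice that makes the sum well-defined at stride or
channel changes. Encoder blocks 2+ halve the spatial grid with a
stride-2 first convolution; channel width doubles per level from
`base_filters` (32 → 64 → 128 → 256 for the default 4-block encoder)
to `base_filters · 2^depth` at the bridge (512 at 16×16 for a 256-px
input). Decoder blocks up-sample ×2 with nearest-neighbour
interpolation, concatenate the mirror encoder output (up-sampled
features first, then the skip — the order is arbitrary but fixed),
and apply a residual unit back down to the mirror's width. The head
is a 1×1 convolution to one channel followed by a sigmoid, giving the
per-pixel fluid probability. Every decoder block, including the
deepest one, concatenates its mirror encoder block; with five blocks
the extra depth is added at the deepest level (bridge at 8×8).

Weights are He-uniform initialized from a seeded generator; biases
start at zero. `layer_shapes` computes the declared output size of
every layer by pure arithmetic, and the test suite asserts the built
network realizes exactly those shapes for all supported configurations
(2–5 blocks × 2–4 convolutions per block). Parameter counts are
reported exactly (trainable: conv weights/biases, BN scale/shift;
non-trainable: BN running statistics); published totals for this
architecture family are not derivable from the printed layer tables
alone (bias and BN bookkeeping conventions are underdetermined), so
counts are reported rather than matched.

## Training

The loss is an equal-weight sum of pixel-mean binary cross-entropy and
a soft Dice term computed once per batch,

    L = BCE + (1 − (2·Σ p·g + ε) / (Σ p + Σ g + ε)),   ε = 1,

with gradients taken with respect to the logits (softplus form of BCE
for stability). ε = 1 keeps the Dice term finite and near zero on
all-empty batches, which matters because most slices in a balanced
set contain no fluid. Optimization is Adam at learning rate 1e-4 with
batch size 16; batch order reshuffles every epoch from a per-epoch seed
derived from the run seed, so runs are bit-reproducible on CPU.

Epoch selection follows a k-fold protocol (k = 5 by default) over the
*augmented* training set, stratified on the per-slice ascites flag:
k models are trained for the full epoch budget, the validation cost
(the combined loss) is averaged across folds per epoch, and the epoch
with the lowest mean cost is selected (ties to the smaller epoch).
The final model retrains on the whole training set for exactly that
many epochs. Because folds are drawn over augmented images, augmented
copies of one source slice can cross folds; a subject-level split
isolates the held-out test set, which is the leakage that matters for
reported numbers.

Numerical engine: no deep-learning framework is assumed. The package
carries a compact numpy CNN engine (`ascites_resunet.nn`) with
channel-first (C, N, H, W) activations so convolutions flatten to
single BLAS sgemm calls — stride-1 3×3 convolutions by shift-and-GEMM
over the nine kernel taps, strided/1×1 convolutions by a channel-first
im2col — plus manual backprop through BN/ReLU/up-sampling/concat and
an Adam implementation. Batch-norm uses ε = 1e-3 and running-stat
momentum 0.9, chosen so inference statistics converge within the
few-hundred-step runs this package targets. Analytic gradients are
verified against central finite differences in the test suite.

## Evaluation

Per-image IoU uses the fluid-free conventions: empty truth with empty
prediction scores exactly 1; empty truth with any predicted pixel
scores exactly 0; otherwise |∩| / |∪|. mIoU averages over all
evaluated slices, controls included. Probability maps are binarized at
0.5 (inclusive ≥).

Detection must work where no ground truth exists, so each slice is
scored by its predicted-positive pixel fraction and declared positive
when the score is ≥ the declaration threshold (inclusive). Sweeping
that threshold yields the ROC; AUROC is the trapezoidal area, which
equals the Mann–Whitney pair-concordance statistic with ties counted
1/2 (asserted against an exhaustive pair oracle in tests). A
truth-dependent variant (thresholding the per-slice IoU itself) is
provided for validation-set analysis only. From the confusion counts,
sensitivity, specificity, accuracy, balanced accuracy, precision and
F1 follow the standard formulas; undefined denominators raise rather
than returning silent zeros, and tabulated comparisons round half-up
to two decimals.

Volume is Σ over slices of (positive pixels × pixel area × slice
thickness) / 1000, in millilitres; when masks were down-sampled the
pixel spacing must be rescaled accordingly (×2 per axis for
512 → 256). The estimate is additive over slice partitions.

## Synthetic phantom

The phantom generator renders schematic abdominal cross-sections: an
elliptical body (semi-axes ≈ 0.42/0.46 of the grid) with a
subcutaneous fat shell (−95 HU), soft-tissue interior (45 HU), and
ellipse-based organ analogues (contrast-enhanced liver 100 HU, bowel
35 HU, paraspinal muscle 55 HU, spine 700 HU, each with Gaussian
texture). Ascites pockets are flank crescents (an outer ellipse minus
an inner offset ellipse — fluid layering in dependent recesses) or
dependent blobs, filled uniformly in [0, 20] HU; only pockets enter
the ground-truth mask. Pockets may be specified by an exact pixel
count (`area_px`), rasterized by growing elliptical shells with a
stable tie-break, so mask arithmetic is exact in tests. Confounders
reproduce the two reported failure modes — a fully distended bladder
(pelvic ellipse) and an ovarian cyst over 3 cm — using the same fluid
HU band, so intensity alone cannot solve the task (a naive HU
threshold demonstrably fails on confounder slices). Gaussian noise
(default sd 10 HU) is added and values are rounded to integers, as CT
reconstructions are, which also makes 16-bit DICOM round-trips exact.
Defaults: 512 px grid, 0.74 mm pixels (≈ 38 cm field of view / 512),
5 mm slices. Pocket size grades span ~0.5–8 % of the body area; the
small/moderate/large strata are arbitrary, as no quantitative
definition exists.

What the phantom does *not* emulate: reconstruction kernels, beam
hardening, partial-volume boundary mixing, multi-phase contrast,
anatomical shape variation. Passing tests therefore demonstrate the
pipeline's mechanics and the architecture's ability to use shape and
location, not clinical-grade performance on patient CT.

## Scaled-down study conditions

Tests exercise the full pipeline at a desk scale chosen once for a
single-CPU budget: 15 ascites + 15 control subjects × 10 slices at
128 px, subject-level 8:2 split, augmentation/balance to 300 slices
per class (~2.5× the source slices; the cohort-scale reference
protocol augments ~7.7×, and the target here is the largest that
keeps the run in a desk-scale budget), a reduced 2-block/base-8
network, and 10 epochs under the standard protocol (Adam 1e-4, batch
16, BCE+Dice). Cross-validated epoch selection is exercised on a
small separable toy problem; the scaled-down run trains with an
explicit epoch budget. Cohort-scale accuracies reported for patient
data are out of reach at this scale by construction; the held-out
phantom assertions (mIoU, detection AUROC, margins over an untrained
network) are the property-based replacement.

## Known limitations

- The numpy engine is CPU-only and tuned for small models; it is not a
  general training framework.
- The phantom's organ geometry is fixed up to jitter; a model could
  exploit layout regularities a patient cohort would not offer.
- Detection by predicted-area fraction is one interpretation of a
  declaration rule that is ambiguous at inference time; the
  truth-dependent variant is available for validation analysis.
- mIoU includes fluid-free slices under the 0/1 conventions, so a
  single spurious pixel on a control slice costs a full point — the
  metric is deliberately strict about false-positive speckle.
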