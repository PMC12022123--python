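# Methods

## Problem setting

The package addresses automatic delineation of head-and-neck gross tumor
volumes on 3D scans acquired before radiotherapy (pre-RT) and midway
through it (mid-RT).  Two structures are segmented per scan: the primary
tumor (GTVp, label 1) and metastatic lymph nodes (GTVn, label 2), against
background (label 0).  The mid-RT task is harder — tumors shrink and
deform under treatment — but a registered pre-RT scan and its contour are
available as a spatial prior, and the central question the architecture
answers is how to inject that prior into the segmentation network without
letting it dominate.

## Networks

**Basic segmentation network.**  A VNet-style residual encoder–decoder
with six resolution stages.  Each stage applies two 3×3×3 convolutions
with instance normalization and LeakyReLU (slope 0.01) around a residual
shortcut (1×1×1 projection on channel change); stages are linked by
strided-convolution DownPool blocks and, in the decoder, by
transposed-convolution upsampling (kernel = stride) with skip
concatenation.  Because voxels are anisotropic (1.2 mm through-plane
versus 0.5 mm in-plane), the x and y axes are pooled at every one of the
five stage transitions while z is pooled only at the last three, so a
56×224×160 patch reaches a 7×7×5 bottleneck.  Four 1×1×1 deep-supervision
heads emit 3-channel logits at the four finest decoder resolutions.
Default widths are (32, 64, 128, 256, 320, 320); tests and CPU probes use
4-stage variants with widths (4, 8, 8, 16).

**Dual Flow UNet (DFUNet).**  Two encoders with the same stage layout: a
primary stream for the 1-channel mid-RT image and a secondary stream for
the 2-channel prior (registered pre-RT image, prior label map rescaled to
{0, 0.5, 1}).  At every encoder stage a CNN cross-attention block gates
the secondary features with a channel gate (global-average descriptor →
bottleneck MLP of 1×1×1 convolutions, reduction ratio 2 → sigmoid) and a
spatial gate (channel mean and max → 3×3×3 convolution → sigmoid), then
adds them residually to the primary features.  One decoder consumes the
fused primary skips.

The residual fusion branch is multiplied by a learnable scalar initialized
to **zero**, so a freshly built DFUNet computes exactly the basic network
on its primary input.  This stabilizes early training (the prior is phased
in only as its usefulness is learned) and makes the fusion wiring
testable: with the primary weights copied from a basic network the two
forwards agree to machine precision.  The gate convolutions themselves are
He-initialized; zero-initializing them would silence gradients into the
bottleneck MLP.

Open wiring choices resolved here: channel and spatial gates both act on
the secondary features (not the primary or the concatenation), gates are
applied multiplicatively in sequence, and only primary-stream skips reach
the decoder.  All of this sits behind `FusionSpec`, so alternative
readings are one subclass away.

## Losses

Raw patches are supervised at `l = 4` (or `deep_supervision_heads`)
decoder resolutions, finest first:

    Loss_raw = Σ_{d=0}^{l-1} (1/2^d) · [ L_CE(x_d, y_d) + L_Dice(x_d, y_d) ]

The 1/2^d weights are used exactly as written (unnormalized); both the CE
and the Dice term sit inside the weight.  Low-resolution targets come from
strided-slicing (nearest-neighbor) downsampling.  The soft Dice is pooled
per class over the whole batch, averaged over all classes including
background, with smoothing ε = 1e-5.  MixUp-generated patches carry soft
labels and are scored with cross-entropy only, at the finest resolution —
soft labels have no meaningful overlap structure for a Dice term.  The
MixUp half of a batch contributes with weight 1 relative to the raw half.

## Augmentation

**MixUp** forms x̃ = λ·x_i + (1−λ)·x_j and the same convex combination of
one-hot labels, λ ~ Beta(α, α) with α = 0.2 (common MixUp practice; the
shape is configurable).  Within a raw mini-batch of B patches each patch
is paired with a random distinct partner, producing B mixed samples, so
the effective batch is 2B (2 raw + 2 mixed at the default B = 2).  MixUp
runs after spatial augmentation, before the forward pass.  The motivation
is patch-level class sparsity: many sampled patches are all-background,
and mixing them with foreground-bearing partners gives every example a
soft foreground signal.

**Bézier intensity transforms** (pre-training-style domain
generalization): intensities are min-max scaled to [0, 1], mapped through
a cubic Bézier curve with endpoints pinned to the diagonal and two
interior control points drawn uniformly on the unit square (the monotone
branch is resolved by sampling the curve at 1024 points and enforcing a
non-decreasing abscissa), optionally contrast-inverted with probability
0.5, then rescaled.  Disabled by default; enabled via
`TrainConfig.bezier_prob` for harmonized-CT pre-training runs.

Standard patch augmentation: per-axis flips (p = 0.5), additive Gaussian
noise (p = 0.15, σ = 0.1 in Z-score units) and global intensity scaling
(p = 0.15, factor 0.85–1.15); labels see only the spatial components.

## Preprocessing

MRI-style branch: body mask (intensity > 60, largest 3D connected
component, in-plane disk-radius-2 closing, 3D hole filling, largest
component again) → tight crop along y and x → Z-score over the whole
cropped volume (a masked variant is available; the global default is the
conservative choice where the convention is unstated) → resampling to
1.2 × 0.5 × 0.5 mm (cubic B-spline for images, nearest-neighbor for
labels; output shape = round(shape·spacing/target)).  CT-for-pretraining
branch: the same, with histogram matching to an MRI reference inserted
before the Z-score.  Histogram matching is a 256-level monotone quantile
mapping; it can only shrink the Kolmogorov–Smirnov distance to the
reference and never reorders voxels.  Every crop is recorded as half-open
0-based bounds so predictions can be mapped back to the original grid
exactly.

## Training

SGD with Nesterov momentum 0.99, initial learning rate 0.01 decayed as
lr·(1 − epoch/total)^0.9, weight decay 3e-5; raw batch 2 (effective 4
with MixUp); foreground-centered patch sampling with probability 1/3 by
default (the probes below raise it to 0.5 — four-case cohorts make
background-only sampling wasteful).  Reference-scale runs use 1000 epochs
of 250 iterations and 56×224×160 patches; those sizes, like everything
else, live in `TrainConfig`.  Cases are split by a seeded shuffle into k
near-equal validation folds; the best checkpoint per fold is the one with
the highest mean aggregated DSC over the two lesion classes on the
held-out cases, and cross-fold ensembling averages the softmax
probabilities of the per-fold best models.

Everything is driven by `numpy.random.Generator` streams derived from the
config seed, and the tensor engine is plain numpy, so a repeated run
reproduces the loss trajectory bitwise.

## Inference

Sliding windows with stride 0.5·patch (last window clamped to the
boundary), Gaussian center weighting (σ = patch/8), softmax probabilities
accumulated and weight-normalized; volumes smaller than a patch are
zero-padded and un-padded.  Flip TTA averages over all subsets of the
configured flip axes (8 variants for {z, y, x}).  Ensembles average
probabilities, not logits.  Labels are per-voxel argmax with ties resolved
toward the lower class index, then mapped back to the original grid
(nearest-neighbor resample + paste into the recorded crop).

## Evaluation

Per-case DSC = 2|P∩R| / (|P|+|R|), with the both-empty case defined as 1
and flagged.  The cohort score is the **aggregated DSC**, pooling
intersections and sizes across cases before forming the ratio — the
convention of the head-and-neck challenge lineage; empty-empty cases
contribute zeros to both sums.  The per-case mean is reported alongside
for transparency.  Scoring happens on the original image grid.

## The phantom cohort

Synthetic cases stand in for paired pre/mid scans: an ellipsoidal body
(tissue level 150, air 10, Gaussian noise σ = 8) on the anisotropic
1.2 × 0.5 × 0.5 mm grid (default 40×96×96 voxels), carrying up to one
GTVp (semi-axes 4–8 mm, contrast +120) and up to three GTVn (3–6 mm,
contrast +60).  The two classes deliberately differ in size and contrast —
a tumor and a node are distinguishable structures, and identical
appearance would make per-class segmentation ill-posed.  The mid volume
reuses the body with each lesion shrunk by a factor drawn from [0.6, 0.9]
and shifted by ≤ 2 mm (clamped so it keeps overlapping its parent),
emulating treatment response on registered grids.  Lesion image edges are
Gaussian-smoothed (σ = 1 voxel) while masks come from the analytic
pre-smoothing geometry, so the targets are not trivially sharp.
Everything is deterministic in (seed, case id).

What the phantoms do **not** emulate: MRI physics (bias fields, coil
profiles), anatomy (airways, bone, muscle texture), irregular tumor
shapes, registration error between time points, and inter-scanner
intensity variation.  Passing the end-to-end probes therefore shows the
pipeline is wired correctly and can learn separable 3D structure — not
that it reaches clinical-grade accuracy on real scans.

## Problem sizes used by tests and the acceptance script

CPU probes train 4-stage, (4, 8, 8, 16)-channel networks on four phantom
cases with 8×32×32 patches for 60 epochs × 20 iterations — small enough
for minutes-scale single-CPU runs, large enough that an incorrectly wired
network demonstrably fails to reach the 0.8 validation-DSC bar.  On the
streamed patch loss an irreducible boundary term remains (smoothed image
edges vs. crisp labels), so "loss goes to zero" is checked on a fixed
memorizable batch while the streamed loss is required to collapse by more
than 70%.

## Known limitations

* The engine is single-threaded numpy; reference-scale (six-stage,
  56×224×160) training is out of CPU reach, and the package is validated
  at reduced scale by design.
* No post-processing (e.g. largest-component filtering) of predictions.
* No deformable registration: mid/pre pairs are assumed voxel-aligned, as
  the phantom generator guarantees and challenge data provides.
* The aggregated-DSC empty-empty convention (contribute zeros) is one of
  two defensible readings; both the flag and the per-case table make the
  affected cases auditable.
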