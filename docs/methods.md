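# Methods

This note documents the models and procedures implemented in `hiwsi`, the
choices made where the design was genuinely open, and what the synthetic
test substrate does and does not demonstrate.

## Tile extraction

Slides are rasters (tiled TIFF or PNG) with the physical resolution carried
in the manifest (`mpp`, µm/px), not in the file header; masks are binary
rasters at any integer downsample of the slide grid (`mask_downsample`
column, default 1). Coordinates are 0-based level-0 pixels; tile boxes are
half-open; the scan is row-major (y outer, x inner) with stride = tile size
(1024 px), so tiles partition the covered region and the accepted list is
deterministic.

**Background filter.** A patch is rejected when the per-channel medians of
all three RGB channels exceed `median_high` (200) or all fall below
`median_low` (100). The all-channels quantifier is a deliberate reading of
an under-specified rule: it discards uniform white/black artifacts without
dropping eosin-dominant tissue in which a single channel alone is bright.
The stricter any-channel variant is available as
`FilterConfig(reject_if_any_channel=True)`.

**Tumor rule.** `tumor_fraction` is the mean of the binarized mask over the
nearest-pixel image of the tile box on the mask grid (no interpolation),
and the acceptance rule is strict: a tile at exactly 50 % tumor is
rejected. The background filter runs first only because it is cheaper; the
two filters commute.

No stain normalization is performed anywhere.

## Patch hierarchy

Each accepted tile yields P_l (full 1024 px → 224), P_m (center crop
[256, 768)² → 224) and P_s. P_s uses selective sampling: the four 256-px
quadrants of the center crop are scanned top-left, top-right, bottom-left,
bottom-right, and the first one passing the color filter is kept; if none
passes the entire triple is discarded. Two pinned choices:

* the "color threshold" of selective sampling reuses the background
  filter's median bounds (the only thresholds defined anywhere in the
  pipeline); it is a config knob (`HierarchyConfig.color_filter`);
* the quadrant scan order is row-major; "first of four" requires *some*
  fixed order for reproducibility.

All reductions are exact area averages: output pixel i of a S→T resize is
the mean of the source interval [i·S/T, (i+1)·S/T), implemented as a cached
row-stochastic weight matrix applied to both axes in float64. Area
averaging is the standard anti-aliasing choice for reductions near integer
ratios and makes constants exact fixed points.

Effective resolutions follow mpp · source/target: at 0.549 µm/px native,
the three views sit at 2.510, 1.255 and 0.627 µm/px.

## Model

The built-in `tiny` backbone encodes a 224² patch as follows: the patch is
divided into an 8×8 grid and each cell contributes per-channel mean,
standard deviation and mean absolute deviation (576 features, a fixed
parameter-free transform); a trainable Linear (the patch-embedding stage)
maps these to D = 64; then B = 4 residual MLP blocks
(x + W₂·GELU(W₁x + b₁) + b₂, hidden 2D) and a final LayerNorm. The three
dispersion statistics matter: mean captures tone and low-frequency
structure, while std and the mean absolute deviation separate texture
*shapes* at equal variance, which is exactly the information that only
survives at near-native resolution. The three branches never share
parameters.

The fusion head is Linear(3D → hidden=D) → GELU → Dropout(0.25) →
Linear(hidden → 4) — the minimal structure satisfying "linear layers with
GELU activation" plus the stated dropout; depth and width are configurable.

**Freezing.** `frozen_block_count(B, r) = ⌊B·r⌋`; freezing marks the
embedding stage plus the first count blocks of every branch non-trainable.
The embedding is frozen only together with at least one block: a 0 % ratio
means a fully trainable model (the natural meaning of the 0 % ablation
point). Frozen parameters are excluded from the optimizer loop entirely,
so they are bit-identical, not merely approximately unchanged.

Head and branch weights initialize from N(0, 0.02²) under the config seed;
biases zero; LayerNorm gains one.

**Feature standardization.** Per-feature z-scoring is fit on each training
fold inside `train()` and stored in the model (applied automatically at
prediction). This is an optimizer-conditioning choice, made up front: block
statistics live on very different scales and AdamW at lr 2·10⁻⁴ would
otherwise need far more iterations.

**`uni-adapter`.** A registry entry with ViT-L geometry (24 blocks,
D = 1024) for externally supplied foundation-model weights. The weights
are gated and not shipped; constructing this backbone without them raises.
No test depends on it.

## Training

Weak supervision: every patch triple inherits its slide's subtype. Class
balancing undersamples each class independently without replacement to
round(rate · n) at the stated rates (MMRd 0.70, NSMP 0.50, others 1.0),
training folds only — the cross-validation driver applies it after the
split, never to test slides. Slide-level undersampling is not applied by
default (only the patch-level rates are quantified anywhere); the rates
map is fully configurable.

Optimization: cross-entropy, AdamW (decoupled weight decay 0.01 — the
conventional default for the optimizer family, recorded in the run
config), lr 2·10⁻⁴ with no schedule, batch 12, dropout 0.25. Batches come
from a fresh seeded shuffle per epoch-equivalent (remainders dropped at
reshuffle). The reference schedule is 20 000 iterations per fold; the desk
profile uses 500, which is past convergence on the synthetic cohorts (the
loss plateaus within ~200 steps at their problem size). Runs are
bit-reproducible under the config seed; hand-derived gradients are verified
against central finite differences in the test suite.

## Aggregation and evaluation

Slide probability: mean of per-patch softmax vectors (soft voting),
permutation-invariant, sums to 1.

Cross-validation groups by patient (a cohort with more slides than
patients must never let one patient straddle train/test) and stratifies by
subtype at the slide level as closely as grouping allows, via a seeded
stratified group k-fold; when a class has fewer slides than k,
stratification is infeasible and a plain patient-grouped split is used
with a warning.

AUROC is computed in rank form (equivalent to pair counting with half
credit for ties). Macro AUROC is the unweighted class mean. CIs are
mean ± 1.96·sd/√k across fold values, clipped to [0, 1] — the simplest
defensible reading of per-fold reporting; a bootstrap percentile interval
over fold values is available (`method="bootstrap"`). Threshold metrics
derive from argmax calls (ties break to the lowest class index); cells
with zero denominators are NaN, never 0, and are excluded from macro
averages with a warning. Mean ROC curves are linear interpolations of fold
curves on a fixed FPR grid (step 0.01) with endpoints pinned to (0,0) and
(1,1); the interpolation flavor affects plots only, not AUROC.

## Synthetic cohorts

The generator emulates the *statistical* structure the pipeline consumes,
not H&E appearance:

* geometry: a bright background band (all channels > 230, left quarter of
  the slide), tissue elsewhere, and a full-height tumor rectangle covering
  `tumor_coverage` (default 0.6) of the tissue area — masks are exact;
* grouping: per class, round(f·n/(1+f)) patients hold two slides so that a
  fraction ≈ f of patients are multi-slide (default 0.125, matching a
  cohort with slightly more slides than patients);
* base appearance: tissue tone (186, 148, 178) plus N(0, 8²) pixel noise;
* coarse pair (MMRd vs NSMP): a ±20 tone on the ring of each 1024-px tile
  outside its central 512×512 — ≥256-px features visible to P_l's field of
  view and, by construction, to no other scale;
* fine pair (p53abn vs POLEmut): single-pixel ±50 dots at density 0.1
  versus i.i.d. Gaussian noise with the same per-pixel variance
  (50·√0.1 ≈ 15.8). Mean and variance match at every scale; the two
  textures differ only in distribution shape, which the near-native P_s
  view retains and the ~4.57× area average of P_l washes out to
  near-Gaussian (central limit).

A per-slide seed is the cohort seed XOR a 31-bit blake2b hash of the slide
id, so regeneration — including partial regeneration — is byte-identical.

This design makes an intensity-histogram classifier separate the coarse
pair on P_l but not on P_s, and the fine pair on P_s but not on P_l (the
test suite checks both directions), which is the substrate for the
ablation ordering: the fused three-scale model must dominate every
single-scale variant because no single scale sees both signals.

What passing these tests does **not** show: robustness to stain variation,
scanner artifacts, segmentation noise, intra-class heterogeneity, or any
real morphology–genotype association. The synthetic signal is deliberately
clean and linearly recoverable; real-cohort performance is a property of
the data and the foundation backbone, not of this code path.

## Problem sizes

End-to-end checks run on a generated cohort of 40 slides (4 × 10) of
4096 px at the 0.549 µm/px default — 16 windows per slide, of which 8 pass
both filters, giving 320 patch triples — with the tiny backbone, 500
iterations per fold, five folds. These sizes are the package's desk-scale
operating point; the reference-scale profile (`reference`) records the
24-block configuration at 20 000 iterations for use with externally
supplied weights.

## Known limitations

* The tumor masks are consumed as given; segmentation quality is outside
  the package's control and never evaluated here.
* The `tiny` backbone's block-statistics featurization is blind to spatial
  arrangement within a patch beyond the 8×8 grid; it is designed for the
  synthetic signal family, not for histology.
* Single-level rasters only; pyramidal level selection and vendor WSI
  formats are out of scope (convert upstream).
* Confidence intervals across five folds are coarse; the bootstrap option
  resamples folds, not slides.
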