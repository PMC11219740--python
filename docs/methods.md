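# Methods

`gliofire` implements a three-stage pipeline for grading brain tumors in
2D MRI slices: morphological background removal, multilevel-threshold
segmentation driven by a firefly swarm, and a parallel 1D+2D CNN that
classifies suspected-tumor regions as high-grade (HGG) or low-grade
(LGG) glioma.  A synthetic phantom generator with exact ground truth
makes every stage testable without access to a clinical archive.

## Preprocessing

Each slice is min–max normalized to [0, 1], histogram-equalized,
resized to the working resolution with bilinear interpolation, and then
background-stripped: binarize at τ = 0.05 of full scale (ties to
foreground), erode the binary mask with a flat 3×3 minimum filter
(replicate border padding), keep the largest 8-connected component,
fill its interior holes, and multiply the mask into the gray image.

Equalization uses the 256-bin cumulative histogram of the 8-bit
quantization with the classic normalization (cdf − cdf_min)/(1 −
cdf_min).  The cdf_min subtraction pins the darkest occupied gray level
at 0; this matters because equalization runs *before* background
binarization, and a plain-cdf mapping would lift a dark background to
its cumulative mass (≫ 0.05) and destroy the brain mask.  A constant
image is a fixed point.  Erosion is applied once, with no compensating
dilation, so the recovered brain mask is a one-pixel-eroded version of
the true one; on 200×200 phantoms the Jaccard overlap with ground truth
is ≈ 0.96.

## Segmentation

A candidate solution is a vector of K thresholds on [0, 255] (K = 5 by
default), kept sorted ascending to remove the K! encoding symmetry.
Each brain pixel joins the threshold nearest in absolute intensity
difference (ties to the lowest index, which makes duplicate thresholds
inert).  Intensity clusters are then decomposed spatially: 8-connected
components larger than 5% of the brain area become unique segments;
the remaining small components of a cluster share one residual segment
so that the criteria below are computed over a full partition of the
brain.

Segmentation quality is scored by

    fitness = (D_w + E_y) / (α + D_b),        α = 1,

where D_w is the mean over segments of the mean absolute deviation of
pixel intensity from the segment mean ("center"), D_b the mean over
segments of the minimum center-to-center gap (0 for a single segment,
penalizing the degenerate solution), and E_y the mean Shannon entropy
in bits of the per-segment 256-bin histograms.  Lower is better.
Segment centers are intensity means, not spatial centroids: every
criterion consumes intensities only.

The firefly swarm minimizes this score with the canonical update on
unit-normalized coordinates — attraction β₀·exp(−γr²) with β₀ = γ = 1,
random walk α·U(−0.5, 0.5) with α = 0.2 decayed ×0.98 per iteration —
clamping to [0, 255] and re-sorting after every move.  A quarter of the
initial population comes from 1-D K-Means on the brain intensities
(distinct sub-seeds per member, so the quarter is diverse), the rest is
uniform random.  The loop is elitist: the best vector ever evaluated is
retained and re-injected, so the best-fitness trace is non-increasing.
Full-scale settings are population 150 and 500 iterations; the swarm
reliably matches exhaustive grid search on two-band toys at population
15 / 30 iterations, and the test-suite studies use population 20 / 50
iterations.

Fitness depends on the induced partition only, so on a two-band image
any solution that separates the bands ties the global optimum exactly;
this makes the exhaustive-grid equivalence check exact rather than
approximate.

## ROI selection

Tumors present as contiguous regions brighter than surrounding tissue,
at least at their rim.  A (non-residual) segment becomes a region of
interest when its mean intensity is at least the brain mean plus
`intensity_k` (default 1.0) brain standard deviations and its area is
between 0.2% and 30% of the brain area — the upper gate rejects whole
tissue bands, the lower one speckle.  If nothing qualifies, a single
whole-brain fallback ROI keeps the classifier fed.  ROIs are ranked
brightest-first; each is cropped at its tight bounding box and resized
(bilinear, aspect not preserved) to the classifier patch size.

## LBP features

Uniform local binary patterns with P = 8 neighbors at radii R = 1 and
R = 2; neighbors at non-integer positions are sampled bilinearly, and
pixels whose neighborhood leaves the patch are skipped.  Codes with at
most two circular transitions get dedicated bins in ascending code
order (58 of the 256 codes), all others share one aggregate bin, for 59
bins.  The patch is divided into a 4×4 grid of cells; each cell yields
an L1-normalized 59-bin histogram, and the R = 1 and R = 2 blocks are
concatenated row-major: 2 × 16 × 59 = 1888 features.  Features are
invariant to additive intensity shifts by construction.

## Parallel CNN

The 1D branch processes the LBP vector with three sigmoid convolution
blocks (kernel/filters 8/16, 5/24, 3/30, each with stride-2 max
pooling); the 2D branch processes the gray patch with three ReLU blocks
(7×7/6, 5×5/18, 3×3/20, 2×2 pooling, 'same' padding).  Both end in
fully connected layers of 100 and 2 units.  The 2D branch, whose
activations are uniformly ReLU, keeps a ReLU after FC1; the 1D head is
linear — a logistic squashing there reintroduces the optimization
plateau described below without adding expressiveness the task needs.
The two 2-unit outputs are concatenated and a trainable 4→2
linear map plus softmax gives the class probabilities; single-branch
ablations apply softmax directly to that branch's FC2 output.  Slice
predictions average softmax outputs over the slice's ROIs.

Training is joint and end-to-end: softmax cross-entropy, Adam
(lr₀ = 0.005, β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch 32, L2 weight
decay 1e−4, global L2 gradient clipping at 1.0, and learning rate ×0.9
after each epoch (the 10%-per-epoch reading of the exponential
schedule; a ×0.1-per-epoch reading would extinguish the rate within
five epochs).  100 epochs at full scale, 30 in the scaled-down study.

Two numerical choices make the deep logistic stack trainable, and both
leave the representable function class unchanged:

* **Init gain 4** on sigmoid-fed convolution weights (Glorot limit
  scaled by the inverse of the logistic slope at 0), so activation
  variance is not annihilated by three squashings.
* **Fixed −0.5 centering** after each sigmoid block.  The logistic
  function's outputs hover around 0.5; that constant component
  dominates every weight gradient beneath it and (empirically) pins
  training at the ln 2 plateau indefinitely, while the centered
  parameterization — equivalent up to a bias shift — trains in a few
  epochs.  This is the classic centered-activation recommendation for
  sigmoid networks.

The implementation is a compact float32 numpy engine (im2col
convolutions, argmax-tracked pooling, seeded initialization and
batching), so training is bit-reproducible for a fixed seed.  Layer
gradients are verified against finite differences in the test suite.
`count_parameters` reports totals for any configuration (712,580 for
the 1D branch at F = 1888; 1,256,580 for the 2D branch at 200×200).

## Evaluation

HGG is the positive class.  The suite reports accuracy (percent),
precision, recall, F-measure, Matthews correlation and the critical
success index from the pooled confusion counts; degenerate denominators
yield 0 with a warning.  The MCC denominator is the square root of the
product of all four marginal sums.  ROC/AUC uses the standard
trapezoidal construction.  Cross-validation is stratified 10-fold
(single repetition) at the slice level — all ROIs of a slice stay in
one fold and inherit its label, preventing leakage — and the report
carries per-fold metrics, their mean, and pooled-over-folds values.

## Phantom generator

A phantom slice is a constant dark background (2% of full scale,
safely below the 0.05 binarization threshold) plus an elliptical brain
of 3 concentric tissue bands (defaults 60/110/160), with one or more
planted tumor disks: a 2-pixel rim at 235 (brighter than every band)
around a core at 210 (HGG-like) or 185 (LGG-like).  HGG-like cores add
a smoothed Gaussian random field (σ = 1.5 pixels) scaled to sd 30 —
tissue-scale heterogeneity rather than pixel-iid speckle, because LBP
responds only to the sign structure of local differences and iid
speckle would be statistically indistinguishable from the iid
acquisition noise both classes share.  Additive Gaussian noise
(sd 5) is applied inside the brain and clipped to [0, 255]; band
intensities are required to be ≥ 4 noise standard deviations apart so
planted thresholds stay recoverable.  Dataset generation draws
per-sample seeds from a master seed and mildly jitters brain axes and
tumor radius; `floor(n × balance)` samples are HGG-like (500 slices at
balance 0.51 gives the 255/245 split).

What the phantoms do *not* emulate: MRI bias fields, partial-volume
effects, anatomical texture inside tissue bands, multi-modal channels,
and 3D continuity.  Passing the phantom study therefore demonstrates
that the pipeline's stages compose correctly and that the classifier
can exploit the intensity and texture contrasts the generator plants —
not clinical-grade performance on real BRATS volumes.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run a scaled-down version of
the full study: 200 slices at 96×96 (tumor radius 9), firefly
population 20 with 50 iterations, 32×32 ROI patches, 30 training
epochs, 5-fold cross-validation, plus the toy-image oracle checks.
These sizes were chosen as the smallest at which every stage still
operates in its intended regime (≥ 3 × minimum-segment-area tumors,
non-trivial folds, converged swarm); the full-scale defaults in
`configs/default.yaml` remain available through the CLI.

## Known limitations

* The firefly update rule is the canonical one; the source description
  of the segmentation algorithm names the metaheuristic without stating
  update equations, so exact step-for-step equivalence with any other
  implementation cannot be claimed.
* ROI gate thresholds are heuristics calibrated to the phantom's
  contrast structure; real data will need per-protocol tuning of
  `intensity_k` and the area band.
* The NIfTI reader extracts single axial slices; no volumetric
  processing.
* With very small brains (≲ 64×64) the one-pixel erosion bite is a
  visibly larger fraction of the mask; brain-recovery guarantees are
  stated at the 200×200 working resolution.
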