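# Methods

This note documents the models, conventions and numerical choices behind
`nucseg`, in the order the pipeline runs.

## Data model

An `InstanceSet` is an ordered list of per-object pixel-coordinate arrays on
one canvas with unique positive labels. Objects **may overlap** — raw
detector output can, and the "remove contained objects" rule is only
meaningful with overlap. A flat label image is therefore a lossy view;
flattening is defined as last-object-wins and is exactly invertible only for
non-overlapping sets. Coordinates are 0-based `(row, col)`; the run-length
encoding alone is 1-based column-major to stay bit-compatible with the
Kaggle DSB submission dialect. Label images are 16-bit single-channel
(more than 255 nuclei per image occur in real data). Per-object coordinate
storage (rather than one label raster) is an artifact decision.

## Toy data generator

`make_toy_dataset` emulates fluorescence-like microscopy: non-overlapping
rasterized ellipses (eccentricity ≤ 0.5, 1 px clearance) with controlled
equivalent diameter, a smoothed two-level intensity field (foreground 0.8,
background 0.15 by default, Gaussian blur σ = 1) plus Gaussian noise
(σ = 0.03). Ground truth is exact by construction and everything is a
function of the seed. What it does **not** emulate: uneven illumination,
touching/overlapping nuclei, texture inside nuclei, debris, or histology
color. Tests passing on these fixtures demonstrate the machinery is correct
and calibrated, not that any backend generalizes to real tissue.

## Size normalization

The "typical nucleus size" is the **median** equivalent-circle diameter
`2·sqrt(area/π)` over detected objects — median rather than mean for
robustness to merged blobs and debris (configurable at the call site). The
scale factor is `target / estimated` with a 40 px target, the operating
point at which detection networks perform best. Images are resampled with
bilinear interpolation (anti-aliased when shrinking); masks per object with
nearest-neighbor so labels are preserved and never invented; objects whose
mask rounds to zero pixels at strong downscaling are dropped. Fixed-canvas
preparation pads small images with zeros anchored top-left and tiles large
ones at 512 px with 50% overlap (the last tile flush with the border);
`stitch_tiles` pastes tiles back last-wins. Padding value, anchoring and
overlap are artifact conventions.

## Style clustering

Features per image (fixed 21-element vector): per-channel mean/sd/1st/50th/
99th-percentile intensities (grayscale replicated to three channels so gray
and RGB inputs share one feature space), gray-level co-occurrence contrast,
correlation, homogeneity and entropy at two 1-px offsets (right and down)
averaged — making them invariant to 90° rotation — on a 32-level
quantization, mean Sobel magnitude, and Otsu foreground fraction. A constant
border is trimmed before measurement so uniform padding cannot shift the
features; a fully constant image yields zero-variance/zero-entropy terms
(correlation defined as 0 when marginal variance vanishes).

Pairwise similarity: when labeled same-condition/different-condition pairs
exist, a small fully connected classifier (one hidden layer of 16 units,
lbfgs) on |a−b| of z-scored features — symmetric by construction. Without
labels, the fallback is `exp(−d²/s²)` on standardized Euclidean distance
with `s` the median pairwise distance. The similarity matrix is
symmetrized with unit diagonal, and its rows are the embedding clustered by
k-means (10 restarts, seeded). The cluster count is
`k = min(n, max(1, round(n/15)))` — about one cluster per 15 images, which
deliberately over-segments so distinct conditions are rarely mixed and which
reproduces k = 134 on a ~2,000-image set. Clusters smaller than a
configurable minimum (default 2) are excluded from synthesis: statistics
from a single image are usable but fragile, and the threshold is our
convention, not an external one.

## Mask synthesis and rendering

Object shapes come from two sources, mixed by a per-object Bernoulli draw
(default 0.5): (a) a `ShapeDB` of real masks cropped to bounding boxes with
recomputable descriptors, fetched by nearest equivalent diameter among a
random subset of 8 and nearest-neighbor-resampled to the drawn size; (b) a
parametric simulator producing star-convex patches whose radial profile is
an ellipse modulated by the first four angular harmonics with random phases,
amplitude proportional to an irregularity parameter (default 0.15) —
star-convexity guarantees connected, hole-free shapes. Object count and
diameters are drawn from the style's empirical distributions (so samples
stay within the observed range); placement is rejection sampling (≤ 1,000
retries per object) that forbids overlap and, for the first half of the
retry budget, rejects positions tighter than the smallest observed
nearest-neighbor spacing.

The shipped renderer samples per-pixel intensities from the style's
empirical foreground/background distributions, smooths (σ = 1) and adds
noise (σ = 0.02). It makes no photorealism claim; it exists so the full
pipeline is exercisable end to end, and any learned image-to-image
translation model can replace it behind the same `render(mask, stats, seed)`
contract.

## Post-processing chain

Stages run in a fixed order; each maps valid instance sets to valid instance
sets and only `unet_correct` can grow an object (never the object count).

* `remove_contained`: A is dropped iff its pixels are a subset of a strictly
  larger B's (equal pixel sets: higher label dropped). Idempotent.
* `merge_surrounded(p1)`: the surround fraction of A by B is the share of
  A's boundary pixels (8-connectivity boundary) adjacent to B; strictly
  exceeding `p1` merges A into the best such B, the union keeping B's label.
  Iterated to a fixed point (≤ n passes). `p1 = 0.17` is read as the
  fraction 17% — the only plausible scale for a surround threshold.
  "Surrounded" measured on boundary adjacency is our definition.
* `remove_small(p2)`: area strictly below `p2` px is removed ("smaller
  than" kept strict).
* `unet_correct(p3, p4, p5)`: per object, the band `dilate(p5) \ erode(p4)`
  (3×3 full structuring element) is re-decided from the probability map —
  a band pixel belongs iff probability ≥ `p3`; outside the band membership
  is untouched. Pixels claimed by several corrected objects go to the object
  whose original mask is nearest (Euclidean distance transform), ties to the
  lower label; emptied objects are dropped.
* `remove_low_confidence(p6)`: mean probability strictly below `p6` removes
  the object.

Defaults `(0.17, 44, 0.9375, 1, 1, 0.8)`. Every stage has an off-switch for
applications (e.g. counting) that do not need pixel-precise contours.

### Genetic-algorithm tuning

Real-coded GA over bounds p1,p3,p6 ∈ [0,1], p2 ∈ [0,200], p4,p5 ∈ [0,3]
(margins rounded to integers): tournament selection (size 3), uniform
crossover, per-gene Gaussian mutation with σ = 10% of the range applied with
probability 0.3, elitism of one, fitness = mean DSB score on the training
triples. The initial population always contains the canonical defaults and
a near-identity genome (no merge, no filters, empty band), so the tuned
result can never score below either baseline; elitism makes best fitness
monotone over generations. Defaults: population 50, generations 30; the
tests and acceptance script use population 30 / generations 15 on two
128×128 training images with planted 45-px debris among 69-px nuclei, which
recovers the size threshold reliably in seconds.

## Evaluation

Matching is greedy by descending IoU with one-to-one uniqueness, ties broken
by (gt label, pred label); a pair is a hit iff IoU **strictly** exceeds the
threshold. For thresholds ≥ 0.5 at most one partner per object can exceed
the threshold, so greedy pairing equals exhaustive max-TP pairing (verified
against brute force in tests). `ε = 1e-40` is added to every score
denominator exactly as specified. An image with neither predictions nor
ground truth is scored 1.0 — the raw formula would give 0/ε = 0, but a
perfect prediction of an empty image must not be penalized; this convention
is ours. Set-level scores are means of per-image threshold-averaged scores;
mF1 is the threshold-averaged harmonic mean, not the harmonic mean of mAP
and mAR.

Error taxonomy: computed from the t = 0.5 matching. A split is a ground-truth
object without a single match covered ≥ 30% each by exactly two predictions
(≥ 15% each when three or more contribute); merges are the same rule with
roles swapped. Overlap fractions are normalized by the **covered object's
own area** — the natural denominator for "a significant region of the
object", though the alternative (the covering object's area) is defensible.
"Missed" is a ground-truth object with no match and no prediction covering
even 15% of it (and symmetrically for false detections), so a split object
is not double-counted as missed.

Mask loss is plain mean binary cross-entropy over an m×m ROI with
predictions clipped to `[1e-12, 1−1e-12]` for finite loss on saturated
values.

## Pipeline and backends

Inference per image: pre-segment → estimate diameter (per-image by default;
a dataset-wide median or a user-supplied prior are config options, because
"the typical size in the provided images" is ambiguous between the two) →
rescale → segment at the normalized scale → map instances back to native
resolution → refine → score. Scoring always happens at native resolution so
annotations are never resampled. The classical backend thresholds with Otsu
(flipping polarity when the bright phase covers most of the image), opens
with a 3×3 element, and splits touching objects by distance-transform
watershed seeded at local maxima ≥ 3 px apart; its "probability map" is the
smoothed, normalized foreground mask.

## Problem sizes used in tests

Fixtures are 128–512 px canvases with 2–10 objects; the full-cardinality
synthesis check runs 134 single-image styles × 20 pairs at 128×128
(≈ 30 s); GA tuning uses two 128×128 training images. These sizes were
chosen as the smallest at which each property is meaningfully exercised.

## Known limitations

* 2D only; no z-stacks, no OME metadata.
* The shipped renderer and classical backend are deliberately simple; the
  headline robustness of the approach comes from trained networks, which are
  out of scope here and enter only through the backend/renderer interfaces.
* `stitch_tiles` does not merge object fragments that straddle tile
  boundaries; callers needing whole objects on large images should merge by
  connectivity afterwards.
* The GA fitness surface is piecewise constant in p2/p4/p5; recovered values
  are identified only up to the plateau containing the optimum.
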