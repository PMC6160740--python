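# Methods

This note documents the models and procedures implemented in
`standcount`, the conventions adopted where several reasonable choices
existed, what the synthetic-field generator does and does not emulate,
and the package's known limitations.

## Coordinate and unit conventions

Pixel indices are 0-based `(col, row)` pairs with pixel-center
registration: pixel (0, 0) maps exactly onto the image origin. World
coordinates are centimeters; x increases along columns (across the crop
rows), y along rows of the image, which is the seeding direction. All
physical thresholds are specified in cm and converted through the ground
sampling distance (GSD); pixel-count thresholds are rounded to the
nearest integer, so the 1.16 cm² weed filter is exactly 36 px at the
nominal 0.18 cm GSD (a 35-px object is removed, a 36-px object kept).
Geotransforms or world files whose per-pixel scale is below 0.01 are
interpreted as meters and converted (a 0.0018 m scale reads as 0.18 cm);
plot imagery at coarser than 1 cm/px is outside the package's intended
regime, so the cutoff is unambiguous in practice.

## Vegetation indices and thresholding

Index formulas are applied to raw 8-bit digital numbers, not chromatic
coordinates; ratio indices (NGRDI, GLI) return 0 where the denominator
is 0, which only occurs for pure-black pixels. Otsu's threshold is
computed per plot image: the index raster is linearly rescaled to a
256-bin histogram, the between-class variance is maximised by exhaustive
scan over the 255 candidate splits, ties go to the lowest qualifying
bin, and the selected bin edge is mapped back to index units. Vegetation
is the high side for all four greenness indices used.

## Object cleanup

The cleanup order is fixed: threshold → binarize → label → area filter →
proximity merge. Components are 8-connected (leaves are blobby;
4-connectivity shreds anti-aliased edges) and labeled 1..K in raster-scan
order of each component's first pixel, a contiguity that filtering
operations re-establish by relabeling. The fragment merge unites objects
whose minimum edge-to-edge distance — measured between centers of
boundary pixels — is at most 1.0 cm, taking the transitive closure so
chains of close fragments collapse into one object; pixel sets are
united, never morphologically bridged. Edge-to-edge rather than
centroid distance was chosen because it is the quantity a human
digitising "fragments of the same plant" would judge, and it is directly
checkable by brute force; it is configurable.

## Shape descriptors

F1–F4 derive from the minimum enclosing rectangle, by default the
minimum-area rotated rectangle over the convex hull of the pixel corner
points (an axis-aligned mode is available). F5–F15 are pixel-set
measures with these conventions:

- F15 (border length) counts 4-neighbor pixel edges facing background,
  making it additive over disjoint unions; F9 = F15/(4√F6) and
  F5 = F15/(2(ℓ+w)) with ℓ, w the MER sides in px.
- The moment ellipse uses the population covariance of pixel centers;
  semi-axes a = 2√λ₁, b = 2√λ₂ with the minor axis floored at 0.5 px so
  1-px-wide objects yield finite ratios. F10 = a/b, F14 = 1 − b/a,
  F8 = 4ab/F6, F12 = √F6/(1+√(VarX+VarY)).
- F11 and F13 are membership fractions of pixel centers against the
  analytic fitted figure (centroid-centered, principal-axis-oriented
  rectangle of area F6 and aspect a/b; moment-oriented ellipse rescaled
  to area F6), with F13 = max(0, (2·|S∩E| − F6)/F6). No rasterization of
  the fitted figure is involved.
- F7 (roundness) is the minimum-enclosing-circle radius of the pixel
  corners minus the largest inscribed-disc radius from the Euclidean
  distance transform, in px: zero for a disc, growing with elongation
  and lobedness.

These definitions are exact contracts, testable against brute-force
pixel computations; rotation invariance of the moment-based features is
within rasterization error (<5 % for shapes a few hundred px and larger).

## Segmentation scoring

Predicted and reference masks combine into a 4-valued overlay
(2·reference + prediction): 3 = TP, 1 = predicted-only = FP,
2 = reference-only = FN, 0 = TN. Precision, recall and F-measure are
reported as percentages; overall accuracy and Cohen's kappa come from
the 2×2 confusion matrix with expected agreement from the marginals.
Ratios with zero denominators are reported as missing, never as 0;
rounding to two decimals happens only at presentation.

## Count model

Per-object count models are affine in the shape features. The
collinearity screen visits feature pairs with |r| > 0.8 in decreasing
|r| order and, when both members are still alive, drops the one with the
lower |r(·, y)| (ties keep the lower-indexed feature; the pair-visit
order is this package's convention). Stepwise regression uses partial-F
p-values — entry at the smallest p ≤ 0.05, removal at the largest
p ≥ 0.10, iterated to stability with an iteration cap; requiring
p_enter < p_remove at construction excludes the oscillating
configuration. Estimated plot totals are Σŷ rounded half away from
zero; per-object predictions stay unrounded. Negative ŷ can optionally
be floored at zero when summing (off by default).

An important statistical caveat, visible in both the packaged reference
correlation structure and simulations from it: several descriptors are
so strongly intercorrelated (border length with MER perimeter/area and
pixel count at r = 0.97–0.99; the two length–width ratios at 0.89) that
which member of such a pair survives screening is decided by sampling
noise, not signal. Feature *identity* in the selected triple is
therefore not a reproducible quantity, while the fitted coefficients
*given* a feature set are. The tests and the acceptance script assert
the identifiable parts: the screen always retains density (F12, the one
descriptor without a collinear partner), and a stepwise refit over a
model's own features recovers each coefficient within 3 standard errors
from simulated data (n = 2000).

## Row analysis

Row lines are built in the vector domain: object polygons are dilated by
a 2.0 cm buffer (bridging within-row gaps of roughly one plant spacing
without merging rows 20 cm apart; configurable), overlapping buffers are
unioned, fused polygons with area below the area-median are discarded,
and survivors' centroids become row points. Points are clustered on x by
fitting an N-tooth comb of pitch T (least-squares over a T/200 offset
grid) and refining with 1-D k-means; labels run 1..N left to right.
Same-label points are connected in y order and smoothed with a centered
moving average (default window 5) whose window shrinks symmetrically at
the ends, so straight lines are exact fixed points.

Row spacing x_i is the mean horizontal distance between adjacent lines
sampled at 100 evenly spaced y positions over their common extent.
Spacing statistics divide by the number of spacings (N−1); per-row count
statistics divide by the number of rows (N). Objects are assigned to the
nearest line within 8.0 cm, ties to the lower row index; rows whose
label attracted fewer than two points are flagged degenerate and
excluded from spacing statistics (which widens the adjacent spacing
accordingly — short rows from failed emergence are kept, not discarded).

## Synthetic fields

The generator renders what the pipeline consumes: brown soil with
luminance speckle (correlated across channels, as brightness texture on
real soil is — it largely cancels in the greenness indices) plus a small
independent chroma noise; rows at pitch T (default 20 cm, 8 rows in a
2.0 m × 2.5 m plot at 0.18 cm GSD) with Gaussian per-row offsets;
plant clusters along rows with exponential gaps (mean 8 cm, 2 cm
minimum) and truncated-geometric multiplicities (mean ≈1.6, max 25);
each plant as 2–5 color-jittered leaf ellipses arranged as a rosette;
weeds as green blobs strictly below the 1.16 cm² filter, placed at least
5 cm from plants; optional dark shadow patches. All randomness flows
from one seeded generator; regeneration is byte-identical. Truth records
plant positions, per-cluster multiplicities, true row centers, weed
positions and the exact vegetation mask. The stage-2 preset scales leaf
lengths by √1.5 so rendered canopy cover is ≈1.5× the stage-1 preset's
(measured ratio ≈1.44 at the default seed), at equal plant density of
roughly 370–410 plants per plot.

What the generator does *not* emulate: perspective and mosaicking
artifacts, illumination gradients, specular soil, senescent or
chlorotic leaves, weeds above the filter size, and plant morphologies
beyond overlapping ellipses. Passing end-to-end tests therefore
demonstrate correctness of the pipeline's logic and its statistical
machinery under clean spectral separation — not field-robustness of the
segmentation, which on real mosaics is limited by exactly those effects.

## Problem sizes and runtime choices

The default test and acceptance workloads use full-size 2.0 m × 2.5 m
plots (1111 × 1389 px) for end-to-end and row-recovery experiments (ten
replicate fields for the row statistics), n = 2000 for regression
recovery, and 100 random rasters for the Otsu oracle equivalence; these
sizes give sub-minute to few-minute runs while keeping every sampling
error term (binomial bounds, 3-SE coefficient bands, CV tolerances)
comfortably resolvable.

## Known limitations

- The merge step is O(pairs within radius) on boundary pixels; on masks
  with tens of thousands of speckle components (e.g. heavily
  under-thresholded imagery) it degrades — the intended use is after a
  sane Otsu split.
- Row detection assumes the row count N and pitch T are known (they are
  seeder settings); it does not estimate N.
- The pixel↔world contract supports axis-aligned geotransforms only;
  rotated world files are rejected.
- Built-in count models are field-specific: applied to imagery from a
  different crop, stage or resolution they are biased (on the synthetic
  stage-2 preset the packaged models underestimate by ~15 %), which is
  why the training path from per-object truth is first-class.
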