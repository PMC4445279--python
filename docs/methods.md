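# Methods

## Scope and data model

`puncta3d` quantifies punctate synaptic markers in two-channel 3D
confocal stacks.  Volumes are arrays indexed `(z, y, x)` with voxel
pitch `(dx, dy, dz)` in nm (default 80 × 80 × 400); coordinates are
0-based `(x, y, z)` voxel indices, and a box written `a×b×c` spans
`|Δx| ≤ (a−1)/2`, `|Δy| ≤ (b−1)/2`, `|Δz| ≤ (c−1)/2`.  All odd-sized
windows that reach past the volume border are filled by mirror
reflection (no edge repetition), so border features see plausible
intensities rather than artificial dark padding.  Anisotropy enters in
three places: features and thresholds are computed in-plane
("pseudo-3D"), z-distances in merging/splitting are scaled by `dz/dx`,
and proximity boxes are flatter in z than in xy.

## Adaptive thresholding (RATS)

Each slice is recursively divided into a quadtree (default depth 5,
stopping when a region's edge falls below `leaflet_size`, default 32 px;
integer midpoint splits, odd sizes give the larger first half).  The
threshold of a region is the gradient-weighted mean intensity

    T = Σ G²·I / Σ G²,

where G is the Sobel gradient magnitude (mirror borders) and the sums
run over pixels with `G > λ`, `λ = scaling_factor × min_noise`.
Truncating sub-noise gradients matters: the Sobel response of pure iid
noise has RMS `√24·σ ≈ 4.9 σ`, so without truncation the weighted mean
of a featureless region is dominated by noise and lands just above the
background, turning most of the image into foreground.  A region is
*valid* iff the mean `G²` among its supra-floor pixels exceeds `2λ²` —
its surviving gradients must stand clear of the floor, not graze it.
Invalid regions inherit the nearest valid ancestor's threshold; an
invalid root uses the unconditional global formula, and the slice median
only when the slice carries no gradient at all (a constant slice then
yields an empty mask, since foreground requires `I > T` strictly).
Leaflet thresholds sit at region centers and are interpolated
bilinearly, with constant extension beyond the outer centers, then
clipped to the slice's intensity range.

**Calibration.** `min_noise` is an absolute intensity and cannot have a
scene-independent default, so `calibrate_params` sets it to 2.5× the
wavelet-based noise-sd estimate of the reference slice (the middle
slice, normally the brightest).  With `scaling_factor = 3` the floor is
`7.5 σ̂ ≈ 1.5×` the pure-noise Sobel RMS: featureless regions fall ~35 %
below it, regions with real edges clear it comfortably.

**Pseudo-3D.** One parameter set, validated on the reference slice, is
applied slice by slice with per-slice recomputation.  Near-empty slices
(stack boundaries, typically darker) have no valid regions of their own;
their fallback is anchored to the reference slice's root threshold,
otherwise they over-detect.  The alternative reading — reusing the
reference slice's full threshold surface everywhere — is available as
`reference_field=True`.

Two named parameterizations serve the two roles the mask plays:
`overmask` (min_noise halved; permissive, guaranteed to contain the true
local maxima) supports candidate detection, and the nominal `segmask`
feeds connected-component segmentation.  The segmentation mask
additionally receives an in-plane 3×3 binary opening before component
analysis, removing speckle and the 1–2 px noise bridges that would
otherwise chain separate puncta into one component.

## Features

The anisotropic 3D Haar descriptor mirror-pads each 9×9 plane of a
9×9×3 ROI to 16×16, applies an orthonormal 2D Haar decomposition
(2 levels, periodization), and sums the per-slice coefficient vectors
with weights (¼, ½, ¼) — the middle slice carries the most in-focus
structure.  The output has a fixed length of 256, is linear in the
input, and is invariant to z-flips.  The full raw coefficient set is
used; selecting sub-bands or energies is left behind the config.
A registry exposes extractors by name so alternative descriptors can be
chained; a deliberately weak `intensity_stats` baseline (mean, max,
center voxel) exists for chain-comparison sanity checks.

## Learning

The bespoke classifier is a single-hidden-layer perceptron (default 16
units, sigmoid activations throughout) trained by full-batch
backpropagation of the binary cross-entropy on per-dimension z-scored
features, with *windowed momentum*:

    Δw(t) = −η ∇E(t) + α · mean(Δw(t−1), …, Δw(t−W)),

defaults η = 0.05, α = 0.9, W = 5, 500 epochs, early stop when the
epoch-to-epoch loss decrease falls below 1e−7.  Averaging the last W
updates damps oscillation on the very small training sets this method
uses (50 ROIs); with W = 1 the rule reduces exactly to classical
momentum, which a regression test pins against an independent
re-implementation.  Training is deterministic given the config seed.
A prediction is positive iff its score strictly exceeds 0.5.

Algorithm chains (extractor list + classifier) are compared by
stratified 5-fold cross-validation with pooled accuracy; SVM and
random-forest classifiers are available behind the same interface as
plugins, the MLP being the default.  Stratification is not part of the
original description; it is used here so that 25+25 training sets keep
both classes in every fold.

## Detection

Candidates are voxels that are over-mask foreground and maximal over
their centered 7×7×5 neighborhood; within a connected plateau of equal
maxima only the lexicographically smallest `(z, y, x)` voxel survives
(determinism; the choice is otherwise arbitrary).  Each candidate's
9×9×3 ROI is classified; accepted centers are refined by iterative mean
shift (9×9×3 window, stop at displacement < 0.5 voxel or 20 iterations,
final position rounded) and then merged: while any two centers are
closer than `merge_fraction × expected_size_xy` (default 0.5 × 7 = 3.5
voxels, z scaled by `dz/dx`), the globally closest pair (ties by
smallest `(z, y, x)`) collapses into its score-weighted centroid.
Always merging the globally closest pair first makes the result
order-independent.

## Clump splitting

26-connected components of the segmentation mask are labeled, components
under 8 voxels discarded as noise, and labels renumbered by decreasing
size.  A component holding k > 1 detected centers is split on its xy
maximum-intensity projection:

1. Trace the closed boundary (Moore tracing, clockwise, starting at the
   topmost-then-leftmost pixel).
2. Score every contour point: `w(i)` = foreground pixels in the 5×5
   window centered on point i (windows clip literally at the image
   border — out-of-image is background), and
   `C(i) = w(i−1) + w(i) + w(i+1)` cyclically.  C is high at inward
   notches.
3. Pick the marker M1 with the largest summed (anisotropy-scaled)
   distance to the rest; ties by smallest `(z, y, x)`.
4. Visit contour points A in decreasing C; for each A test chords AB
   (Bresenham rasterization) in decreasing split energy
   `E = C(A)·C(B)/d(A,B)`.  The first chord whose removal leaves M1's
   projected pixel 8-disconnected from every other marker wins — it is
   the energy maximizer for that A.  Chords running through a marker
   pixel are inadmissible.
5. Voxels follow their projection pixel's side; chord pixels and stray
   fragments go to the side whose nearest marker projection is closer.
   Recurse on the remainder with the remaining markers.

Markers whose projection falls off the object (possible after rounding)
snap to the nearest projection pixel first.  If no separating chord
exists at some stage (e.g. marker projections coincide), the remaining
markers share one child flagged *unsplittable*.

**Refined centers.** Every cleanly split child reports its voxel
centroid as the refined punctum position.  Two deliberate edge-case
policies: an unsplittable child passes its guiding markers through
unchanged (collapsing them to one centroid proved destructive on
elongated components where the projection crowds markers together), and
markers not backed by any segmented object also pass through —
segmentation refines positions but does not veto a model detection.
Quantification reports counts and size statistics over objects within
8–1000 voxels.

## Co-localization and evaluation

A detected center is kept iff any morphology-foreground voxel (nominal
pseudo-3D RATS mask of the morphology channel) lies within its centered
9×9×5 box; failures are discarded as staining artifacts.  The filter is
a pure subset operation and idempotent.

Evaluation matches detections to reference centers one-to-one: among all
pairs within the 7×7×5 box, the globally closest (anisotropy-scaled
Euclidean; ties by the detection's `(z, y, x)`) is paired first.
One-to-one matching is stricter than per-marker counting and cannot
double-count two detections against one reference.  Precision, recall
and `F = 2PR/(P+R)` are reported as percentages rounded half-up to two
decimals; multi-region reports append an AVERAGE row of unweighted means
of the (rounded) per-region values, which is the convention the
published tables this package's arithmetic is checked against use.

## Synthetic scenes

The generator emulates the image properties the method is sensitive to:
anisotropic Gaussian puncta (σ_xy = 1.6, σ_z = 0.8 voxels, truncated at
3σ, peaks uniform in 150–250) on integer-voxel centers; fused clumps of
2–3 puncta spaced 1.0–1.5 σ_xy apart (guaranteed to share a foreground
component, and — being closer than 2σ — unimodal, so clump members are
not separable by local maxima alone); a tube-like morphology channel
from a persistent random walk (radius 4 px, mild z elongation standing
in for the PSF); dim artifacts (0.3× median peak) placed far off the
tube; an additive background gradient, a multiplicative stitching-seam
step (factor 0.65–0.85 at a random column; puncta are not placed within
2σ of the seam so ground-truth maxima stay well defined), parabolic z
attenuation (15 %), and Gaussian noise (default 0.1× median peak,
clipped at zero).  Distinct puncta groups keep ≥ 6 px xy Chebyshev
separation when within 2 z-slices of each other, so that a 7×7×5 maxima
search cannot suppress one true center with another — group placement
density, not detector tuning, sets this bound.  Ground-truth labels
assign each voxel inside any 3σ ellipsoid to the nearest center under
the blob Mahalanobis metric.  Generation is bit-deterministic under a
fixed parameter set.

What the generator does **not** emulate: realistic PSF side lobes,
photon shot noise (intensity-dependent variance), intracellular
transport artifacts with punctum-like texture, true stitching
misalignment, or puncta stacked along z within one column.  Passing
tests therefore demonstrate algorithmic correctness and robustness to
the modeled nuisances, not end-to-end performance on real microscopy.

**Benchmark scene.** 256×256×16 voxels, 150 puncta, 30 % clumped, 10
artifacts, seed 42 — small enough that the full pipeline (training
included) runs in well under a minute on one CPU while containing every
structure class the stages must handle.  On it the pipeline reaches
perfect precision with recall bounded by the one-detection-per-clump
ceiling; the acceptance suite asserts final F ≥ 85 % and that
splitting never degrades F.  Training uses 25 positive + 25 negative
ROIs (negatives mix punctum-adjacent voxels ≥ 3 px xy from any center,
background, and artifact centers).

## Known limitations

* Clump members fused below the maxima-search resolution yield one
  detection; splitting can only separate clumps carrying ≥ 2 detected
  centers.
* The quadtree interpolation produces transition bands around strong
  contrast seams; objects inside a band may segment against an
  intermediate threshold.
* The concavity/energy cut is straight; strongly curved interfaces
  between fused puncta are approximated by a chord.
* `min_noise` calibration assumes approximately uniform noise across the
  reference slice.
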