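# Methods

This note documents the models and procedures implemented in `massdesc`,
the defaults chosen where several readings were possible, what the phantom
generator does and does not emulate, and the package's known limitations.

## Pipeline overview

Input is a grayscale patch (PNG/TIFF/DICOM; 0-based, row-major coordinates,
half-open bounding boxes) with a mass bounding box. Stages: optional
contrast augmentation → histogram segmentation → shape, margin and density
descriptors → feature selection → MLP classification under stratified
k-fold cross-validation. A single global seed fans out to per-stage seeds
through a fixed affine derivation (`pipeline.stage_seed`), so any stage can
be rerun reproducibly in isolation.

## Contrast augmentation

Two variants per image emulate scanner-dependent contrast:

* **Gamma correction.** The gray-level proportion
  `ρ = 100·(μ_I + σ_I)/L` classifies an image as bright (`ρ > 70`) or dark;
  bright images get exponent `γ = 0.3`, dark ones `γ = 0.5`. Intensities are
  normalized to [0, 1], exponentiated, rescaled to `[0, L]` and rounded
  half-up, so 0 and `L` are fixed points and pixel order is preserved
  (γ ≤ 1 is monotone). ρ is computed on the full image; a region mask can be
  applied by the caller before the call.
* **Morphological opening** with a discrete disk of radius 5 (Euclidean
  ball, 11×11 support). Opening is anti-extensive and idempotent; it
  flattens bright detail smaller than the structuring element. (It cannot
  *increase* luminance anywhere; it is used purely as a contrast variant.)

## Segmentation

A mass is dense tissue, hence the bright majority structure inside its own
bounding box. The threshold is `median − offset·σ` of the crop (default
offset 1.0, population σ), with strict `>` comparison; a binary opening
(disk radius 3, configurable) removes small artifacts, and the largest
8-connected component survives (area ties broken by earliest raster-scan
label). Degenerate crops (fewer than two gray levels), empty results, and
masks covering ≥ 98% of the crop raise a failure signal carrying the
threshold; the last case is the characteristic failure of the median rule
when the mass is *not* the crop majority — the threshold then falls below
the background mode and keeps everything, and no offset relaxation can
recover it. Callers may retry with a smaller offset for the empty-mask
case.

## Shape descriptors

The mask is thinned with Zhang–Suen skeletonization. Branches shorter than
2% of the mask bounding-box diagonal are pruned (boundary rasterization
sprouts short spurs that would otherwise inflate the endpoint count; the
fraction is configurable). An endpoint is a skeleton pixel with ≤ 1
skeleton neighbor (an isolated pixel counts as one endpoint); bifurcations
are maximal 8-connected clusters of pixels with ≥ 3 neighbors, counted once
per cluster — per-pixel counting would inflate the count at diagonal
junctions. The skeleton center is the skeleton pixel maximizing the
distance transform of the mask (ties: smallest row, then column); mask
centroid and skeleton centroid are available as configuration alternatives.

Features: `IS = Np + Nb`; `n_lobes = max(Np − 2, 0)` — a smooth elongated
mass thins to a two-endpoint line, so the two axial endpoints are
discounted; and sample moments of the endpoint-distance set `p`: mean,
variance (n−1 denominator), standard deviation, adjusted Fisher–Pearson
skewness, and bias-corrected Pearson (non-excess) kurtosis. Fewer than two
distances ⇒ moments reported as 0 with a degenerate flag.

Numerical caveat: thinning is not exactly equivariant under 90° rotation
(subiteration order); endpoint positions can shift by ~1 px. Translation
invariance is exact.

## Margin descriptors

Radii are measured from the mask area centroid to the vertices of the
subpixel marching-squares contour (isoline at 0.5). The subpixel contour
was chosen over a literal boundary-pixel list because it yields smoother
radii and an unbiased perimeter for digital shapes; the radii multiset
semantics are unchanged.

* `MR = (1/n) Σ r̄/(|r_j − r̄| + r̄)` and `RR = r_min/r_max` are exactly 1
  iff all radii are equal, and both live in (0, 1].
* `MOR` estimates `f(r)` by histogram (Freedman–Diaconis bins, 3-bin moving
  average) and integrates between the local minima flanking the global
  mode, falling back to the support bounds. Only *pronounced* valleys
  (smoothed height below half the mode height) count: rasterization jitter
  on a near-constant radius set otherwise splits a unimodal distribution
  (a digital disk measured 0.88 without the depth rule, 1.0 with it), while
  genuinely bimodal radii keep deep valleys. All radii identical ⇒ MOR = 1
  by convention.
* Circularity `4πA/P²` uses the traced contour length as `P`. It is the
  least rotation-stable of the four (re-rasterizing a rotated mask roughens
  the contour; observed shifts up to ~0.07), which is one reason roundness
  `MR`, not circularity, is the selected margin feature.

## Density descriptors

`DM(x,y) = I(x,y)·H(x,y)` with `H` the GLCM homogeneity
`Σ p(i,j)/(1+(i−j)²)` of the window centered at each pixel (default 11×11,
offset distance 1, 32 quantization bins over the patch range). Co-occurrence
pairs are taken along the two axial symmetric directions — the neighbors at
Euclidean distance 1 — which also gives the exact hand value `H = 0.5` on an
adjacent-bin checkerboard; diagonals can be added with `directions="all"`.
A pair belongs to the window of its origin pixel; windows are clipped at
borders. The per-pixel sums are computed with integral images, so the map
is exact and fast.

Clustering is fuzzy C-means with c = 4, fuzzifier m = 2, tolerance 1e−5,
max 300 iterations, implemented directly on the scalar values (weighted by
value multiplicity) with a deterministic quantile initialization; hard
labels by maximum membership, classes renumbered 1..4 by ascending center
(1 = fatty … 4 = high density). A hard k-means switch is provided. Inputs
with fewer than 4 distinct values are assigned classes by value order with
a warning. Clustering is fit per mass on the pixels of the 20%-expanded
box only — each mass is described in its own local context.

`dms` compares the predominant class inside the mask (`cm`) with the
predominant class of the expanded-box ring (`cs`), ties going to the higher
class: equal (2) when `cm = cs` or the two occurrence distributions differ
by ≤ 10% per class on average (L1 ≤ 0.2 — the distributional reading of the
"≤10% difference" rule, since a percentage difference between two small
integers is ill-defined); otherwise high (3) when `cm > cs`, low (1) when
`cm < cs`. `max(cm, cs)` is stored as auxiliary output. Both the gray-level
path (D1) and the density-map path (D2) are computed; D2 is the selected
feature.

## Feature sets and classifier

Named sets: S1 (all shape candidates), S2 `{n_lobes, IS, p_mean, p_std}`,
S3 `{n_lobes, IS}`, M1 (all four margin metrics), M2 `{MR}`, M3
`{MR, n_lobes}`, D1 `{dms_gray, dms_dm}`, D2 `{dms_dm}`, and
FINAL = S3 ∪ M3 ∪ D2 = `{n_lobes, IS, MR, dms}`. Feature relevance is
profiled by Pearson correlation against the integer grade (Spearman
available — grade is ordinal). BINARY maps BR-2/3 → benign and BR-4/5 →
malignant, the standard clinical reading.

The classifier is scikit-learn's `MLPClassifier`: hidden layers (10, 10),
ReLU, softmax/cross-entropy, Adam at learning rate 0.001, 500 epochs,
features z-scored with the training fold's statistics, fixed seed.
Cross-validation is stratified 10-fold; if the smallest class has fewer
members than folds, the fold count drops to that size with a warning.
Multi-class recall/F1 are macro-averaged (the smallest grade class
dominates errors, and macro averaging keeps it visible); balanced accuracy
is the mean per-class recall (binary: mean of sensitivity and specificity);
AUC is one-vs-rest macro over pooled out-of-fold probabilities. No
resampling is applied for class imbalance; a class-weighting switch would
be the first extension.

## Phantom generator

Phantoms exist so that every stage has a ground-truth oracle. A mass body
is a star-convex region `r(θ) = r0·(1 + Σ a_k cos(kθ + φ_k))` (radius must
stay positive: `Σ|a_k| < 1`), rasterized as a polygon, optionally with
narrow radial spicule triangles. The rendered scene has three components:
the mass plateau at the intensity level of its target density class
(levels 40/100/160/220 for fatty/low/medium/high at L = 255), a 4 px dark
fatty moat hugging the mass (the halo sign of circumscribed masses), and a
smoothed Gaussian random field at the background class level elsewhere
(amplitude 3, smoothing σ = 6 px), plus white noise (σ = 4) and mild
in-mass texture (σ = 5, masses are internally heterogeneous). The moat, not
a box-filling gap, is what keeps the surrounding ring dominated by the
background tissue class, so the density relation is well-posed; it also
guarantees the mass is the bright majority structure inside its own crop,
the segmentation's operating assumption.

Annotation boxes frame the mass *body* (2 px pad); spicules may stray past
the box, like narrow spicules straying past a detector box on a real
spiculated mass. Consequently the segmented mask of a spiculated phantom
loses its spicules — measured MR for the spiculated grade reflects only its
lobulation, and grade separation for BR-5 rests on lobe count, IS and
density rather than on a very low MR. Truth-mask MR does drop with
spiculation.

Grades are assigned by generative parameters (the phantom is the oracle, so
labels must be parameter-determined): BR-2 round/slightly oval, 0 lobes,
mass class below surround (low density); BR-3 oval (k = 2 harmonic,
a ∈ [0.08, 0.16], optionally a gentle k = 4 component), low/equal density;
BR-4 lobulated (k ∈ 4..8, a ∈ [0.11, 0.15]), equal/high; BR-5 spiculated
(k ∈ 8..12 plus 8–12 spicules of length 0.22·r0, width 8), mass class high.
Amplitudes are capped near 0.15 because the median-threshold segmentation
requires the mass to fill > 50% of its own box — the geometric budget of a
square box around a star-convex shape. `r0` is drawn from [22, 28] px in
128 px patches; class counts, seeds, and all levels above are fixed
defaults of `sample_dataset`, and the generator is bit-reproducible from
(spec, seed).

What the phantoms do **not** emulate: anatomy (ducts, vessels, pectoral
muscle), X-ray physics and scatter, overlapping fibroglandular texture,
ill-defined/obscured margins, and fat-containing masses. Passing the
phantom suite therefore demonstrates that the descriptors measure what they
claim on controlled geometry and contrast — not clinical performance. Two
known systematic effects on the density-map path: the textured mass
interior lowers its homogeneity, so generative *equal*-density scenes read
as *low* on the DM path (a consistent encoding the classifier absorbs, but
not a recovery of the generative label); and homogeneity jitter scales with
intensity, which is why coarse behavior is insensitive to the quantization
default.

## Problem sizes used in the shipped checks

The property suite validates descriptor formulas on closed-form shapes
(disks, ellipses, bars, checkerboards), density-relation recovery on 100
phantoms with a two-class generative gap, segmentation Dice on 50 phantoms,
and end-to-end grade recovery on 300 phantoms (75 per grade, 128 px
patches) with the full FINAL + MLP 10-fold pipeline — sizes chosen to keep
the whole suite around a minute on one core while leaving each check
statistically meaningful.
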