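# Methods

This note documents the models, conventions, numerical choices and
known limitations behind `busfeat`. It is the design record; empirical
numbers quoted here are exactly the ones the test suite and
`scripts/acceptance.py` recompute.

## Region of interest

The ROI is the tight tumor bounding box expanded by `pad` pixels
(default 30) on each side, in pixel units of the input image.
Coordinates are row-major, 0-based, with inclusive bounding boxes.
When the expansion crosses the image border it is clipped — no
synthetic padding is invented — and the requested pad is recorded on
the patch. Masks with several connected components are reduced to the
largest with a warning (an annotated image is expected to contain one
outlined tumor); empty masks and image/mask shape mismatches are hard
errors. Polygon contours (CSV of `x,y` vertices) are rasterized by
even-odd fill; masks are the canonical internal representation.

## Backbones and deep features

Two backbones sit behind one `BackboneSpec` interface: the standard
VGG19 architecture (16 conv layers in 5 blocks of 64/128/256/512/512
kernels, FC6/FC7 with 4096 units, 224×224×3 input) and a small
`fixture` network (3 blocks of 2 layers with 4/8/16 kernels, two
32-unit fc layers, 64×64×3 input) whose weights are He-scaled normals
drawn from a recorded seed. The forward engine is plain numpy (3×3
same-padding convolution + ReLU, 2×2 max-pool per block, dense ReLU
layers); it runs any spec given a weights mapping, so VGG19 forward
passes only need a `.npz` weights file. The feature-set *sizes* of the
six extraction levels are pure bookkeeping over the architecture and
never require weights. The per-channel max/avg pooling mechanism is
weight-agnostic, which is why the whole pipeline is developed and
tested on the fixture network.

Preprocessing: the ROI is resized bilinearly to the backbone input
(aspect ratio not preserved; configurable in principle, fixed here),
the single gray channel is replicated three times, and the
backbone-native normalization is applied (min–max to [0,255] then
ImageNet channel-mean subtraction for VGG19; min–max to [0,1] for the
fixture network). ROIs smaller than 8×8 are rejected.

Each conv layer yields a 2N vector: N per-channel maxima followed by N
per-channel means, in channel order. Normalization nesting is fixed:
per-layer sets are l2-normalized first, and every concatenation (block,
all-blocks, fc pair, combined) is renormalized afterwards. The order
matters because SVM classification is scale-sensitive; nesting
normalization this way keeps every constituent set on an equal footing
before each concatenation. A zero vector cannot be normalized and is
passed through with a flag and warning. Feature names
(`CONV5_4:max:13`, `FC6:201`) carry complete provenance: level, layer,
pooling type and channel index round-trip from the name alone.

## Texture features

The rectangular ROI (tumor plus margin, deliberately not masked to the
outline) is min–max quantized into G = 32 gray levels (configurable;
the floor-based rule maps a constant image to bin 0). Co-occurrences
are accumulated at 10 distances (1–10 px) and 4 orientations with
(row, col) displacements 0°→(0,+d), 45°→(−d,+d), 90°→(−d,0),
135°→(−d,−d), symmetrized by adding the transpose and normalized to
probabilities: 40 GLCMs. Note that `skimage.feature.graycomatrix`
rounds `sin(angle)·d`, so its diagonal displacement at d ≥ 2 differs
from the (d, d) convention used here; the test-suite cross-check against
skimage therefore covers axis directions at all distances and diagonals
at d = 1.

Twenty statistics per GLCM (800 features total) follow the classical
definitions with 1-based gray-level indices i, j ∈ 1..G, natural
logarithms, and 0·log 0 ≡ 0: autocorrelation, contrast, correlation,
cluster prominence, cluster shade, dissimilarity, energy, entropy,
homogeneity, maximum probability, sum of squares (variance), sum
average, sum entropy, sum variance, difference variance, difference
entropy, the two information measures of correlation (HXY/HXY1/HXY2
construction), inverse difference normalized and inverse difference
moment normalized. Two variant choices are documented rather than
debatable: *sum of squares* is centered on the marginal mean μx (the
GLCM is symmetric, so μx = μy), and *sum variance* is the variance of
the diagonal-sum distribution about the sum average (the modern
convention; Haralick's original text plugs in the sum entropy). A
brute-force double-loop oracle in the tests is authoritative for all
twenty formulas (agreement to 1e-10 on random matrices).

## Morphological features

Eighteen descriptors are computed from the mask/outline in fixed order:
area (pixel count), perimeter, form factor 4πA/P², roundness
4A/(πD²max) with Dmax the maximum Feret diameter, aspect ratio
(bounding-box sides, ≥ 1), convexity (hull perimeter / perimeter),
solidity (A / hull area), extent (A / bbox area), undulation,
compactness P²/(4πA), NRL entropy and variance, and six best-fit
ellipse features (major/minor axis lengths 2a/2b, a/b, ellipse
perimeter (Ramanujan's second approximation) / tumor perimeter,
major-axis angle in [0°, 180°) from the image x-axis, and the Jaccard
overlap between the rasterized ellipse and the tumor).

The boundary is traced at sub-pixel resolution by marching squares and
then lightly smoothed with a 5-point circular moving average: the raw
staircase contour inflates perimeters by ≈ 5% (a disk of radius 50
measures 331 instead of 314), while the smoothed polygon is accurate
to ≈ 0.3%. Perimeter, hull, NRL and undulation all use this one
polygon so the ratios stay internally consistent.

The normalized radial length (NRL) profile is the boundary-to-centroid
distance normalized by its maximum ("tumor center" = pixel centroid).
Its entropy uses a 10-equal-bin histogram on (0, 1] with natural log;
its variance is the ddof = 0 variance of the raw profile (the
convention that matches the hand-computable two-level case: half 0.5 /
half 1.0 → entropy ln 2, variance 0.0625).

*Undulation* quantifies boundary waviness as the number of concave
excursions — maximal runs of boundary points lying more than 1 px
inside the convex hull — divided by the number of boundary samples.
This is an interpretation (the classical reference construction is not
fully specified in the lineage this package follows) and is documented
as such; it is monotone in spiculation on the phantoms.

The best-fit ellipse comes from second-order central moments (the
ellipse with the region's area-normalized moments, semi-axes
2√eigenvalue). A 1/12 pixel-square term is added to the diagonal
moments to stabilize thin shapes, after line-like degeneracy (raw
minimum eigenvalue ≈ 0) has been rejected. On rasterized ellipses the
fit recovers the generator's axis ratio within 3% and angle within 2°.

## Feature selection

mRMR ranking discretizes each feature into three states at
mean ± stdev and uses the MID (difference) criterion: the first
feature maximizes MI with the labels; each next pick maximizes
relevance minus mean redundancy against the already-selected set. Ties
keep the earliest column (stable). Phase 1 scores the nested top-m
groups (m = 1..M) and keeps the smallest group attaining the maximum
MCC; phase 2 backward-eliminates: the removal yielding the highest MCC
is accepted while it does not drop below the current MCC (so the trace
is non-decreasing and ties favor the smaller set; equal-MCC removals
discard the worst-ranked feature), stopping when every removal strictly
hurts or one feature remains.

The subset evaluator is a cross-validated SVM scored by pooled MCC on
folds built once per selection run. Re-running the full 21×19 grid for
every one of the M + n² candidate subsets is intractable, so the
default `fast` mode evaluates each subset at a single working point:
C = 100 with σ set by the median pairwise-distance heuristic of the
subset at hand. A fixed σ is *not* usable here: per-sample l2
normalization places single-feature subsets on scales of 1e-4 and
below, where any preset kernel width is either saturated (kernel
constant to ~1e-8, the classifier collapses) or hopelessly local. The
median heuristic adapts the width to the subset's actual geometry and
C = 100 keeps the evaluation mostly-hard-margin; a pinned pair and a
`full` per-subset grid-search mode remain available. The final selected
subset is always tuned with the full grid.

By default selection runs once over the whole dataset
(`selection_scope="global"`), matching the protocol of the lineage this
package reimplements; this leaks test-fold information into the
selection and optimistically biases the CV estimate. The leakage-free
`"nested"` scope (selection + tuning repeated inside every training
fold, outer folds scored untouched) is implemented and recommended when
the CV number itself is the claim.

## Classification and evaluation

The SVM is `sklearn.svm.SVC` (LIBSVM) with an RBF kernel; the kernel
width σ maps to γ = 1/(2σ²). Grid search covers C ∈ {2⁻⁵…2¹⁵},
σ ∈ {2⁻¹⁵…2³} (399 pairs) and maximizes the MCC *pooled* over the test
folds of a stratified 10-fold CV (pooling chosen over per-fold
averaging; configurable by evaluating a different objective on the
report). Ties prefer smaller C, then larger σ (the smoother model).
Folds are stratified — with imbalanced classes plain splitting risks
benign-only training folds — and reproducible from a recorded seed;
each sample is tested exactly once. Malignant is the positive class
everywhere.

The six metrics are computed from each fold's confusion counts; a
zero-denominator metric is defined as 0 and flagged with a warning.
ROC curves are computed over all decision-score thresholds and AUC by
the trapezoidal rule, which equals the Mann–Whitney statistic
(tested). Paired two-sided t-tests compare per-fold accuracies of two
configurations; identical sequences are flagged undefined (NaN) and a
constant nonzero shift returns p = 0 (degenerate t → ∞).

## Synthetic phantoms

The generator emulates B-mode appearance at desk scale: 160×160 px
images, one hypoechoic lesion per image with boundary
r(φ) = r₀(1 + Σₖ aₖ cos(kφ + ψₖ)) on an elongated (axis ratio
1–1.6, random orientation) coordinate frame, r₀ ∈ [18, 30] px.
Benign-like lesions use harmonics k ∈ [2, 4] with total relative
amplitude ≈ 0.04 (smooth, near-elliptical); malignant-like lesions use
k ∈ [2, 12] with amplitude ≈ 0.18 (irregular, spiculated). The lesion
is 45% darker than the background level of 160 (8-bit scale). Speckle
is the squared magnitude of a complex Gaussian field smoothed with
σ = 1.5 px — the standard Rayleigh-family surrogate for coherent
ultrasound texture — applied multiplicatively and renormalized to unit
mean. Masks are the exact rasterized lesion, star-convex and
single-component by construction, with ≥ 1 px image margin. All
randomness flows from one seeded generator; per-image child seeds stay
below 2³¹.

What the phantoms do show: the full pipeline (ROI → features →
selection → tuned SVM) recovers a known, morphology-encoded class
difference with high CV MCC, selection removes noise dimensions, and
train/test runs on disjoint phantom sets can generalize at full
strength. The generalization entry is the most seed-sensitive number
in the acceptance report: with the combined deep + morphology recipe
at n = 140, mRMR occasionally ranks a weak subset ahead of the
strongly discriminative morphology features and the smallest-argmax
rule of phase 1 then locks onto it, giving matched but mediocre train
and test scores on that seed — a property of greedy selection among
many weakly informative dimensions, not of the classifier. What they do not
show: clinical-grade performance. Real BUS images carry acoustic
artifacts (shadowing, enhancement), heterogeneous parenchyma,
annotation variability and much subtler class differences; phantom
scores are a mechanism check, not a clinical claim, and the clinical
accuracy figures of the source protocol are not reproducible without
the original (non-public) datasets.

## Problem sizes and defaults

The shipped experiment sizes are chosen for a single-CPU desk run: the
headline cross-validation uses 100 + 100 phantoms with the fixture
backbone and the CF3 + morphology recipe (≈ 20 s), the
selection-effect comparison pads 18 morphology features with 150 noise
dimensions at n = 60, and the generalization run trains on 140 and
tests on 60 phantoms. `scripts/acceptance.py` completes in ~1–2 min.

## Known limitations

- The fixture backbone's random-weight features are weakly informative
  by design; on phantoms the discriminative signal enters almost
  entirely through the morphology family, and selection typically
  reduces the combined vector to one or a few morphology features.
- Global-scope selection (the default, protocol-faithful mode)
  optimistically biases CV estimates; use the nested scope for honest
  numbers on new data.
- GLCM gray-level count, ROI masking for texture, and the roundness
  denominator are conventions with competing variants in the
  literature; each is configurable and the defaults are stated above.
- The ellipse-angle feature is discontinuous at 0°/180° and not
  rotation-invariant by nature; rotation-sensitive features (aspect
  ratio, extent, angle) are excluded from the rotation-invariance test
  accordingly.
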