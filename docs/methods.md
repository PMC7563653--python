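# Methods

`nucleoqh` implements a nuclear quantitative-histomorphometry (QH) pipeline
for pathologist-annotated tumor regions in H&E biopsy images: stain
normalization, nucleus detection and watershed segmentation, extraction of
216 morphometric features in four families, a repeated-split feature
identification protocol, and construction/evaluation of a binary
progression-risk classifier. A synthetic nucleus-field generator with
ground truth makes every stage testable without image data.

## Synthetic nucleus fields

Nuclei are ellipse-like polygons placed on a hexagonal lattice perturbed by
isotropic Gaussian jitter (`jitter_sigma`, µm per axis). Placement is
rejection-sampled against bounding-circle overlap (with a 0.25 µm
clearance), so ground-truth contours are guaranteed pairwise disjoint;
~15% more lattice sites than nuclei are provisioned so rejection has
headroom. Each nucleus has a major semi-axis `a ~ N(axis_mean, axis_sd)`
(default 3.0 ± 0.3 µm, i.e. a ~6 µm long axis at the paper-typical scale
of packed prostate-tumor nuclei), a minor/major axis ratio
`~ N(axis_ratio_mean, eccentricity_sd)` clipped to [0.3, 0.95], an axial
orientation drawn von Mises(µ=0, κ=`kappa`) folded to [0°, 180°), and a
boundary perturbed by low-order radial Fourier noise (harmonics 2–4,
amplitude `fourier_amp`, default 0.03) so shape measures have non-trivial
variance. Rendering paints nucleus interiors with a fixed hematoxylin-like
RGB triplet on an eosin-pink background plus additive Gaussian noise
(SD 6); it exercises stain normalization and watershed without modeling
stain physics, scanner artifacts, stroma, glands or touching nuclei —
results on real tissue therefore depend on segmentation behavior the
generator does not probe (overlapping nuclei, chromatin texture,
out-of-focus regions).

The two-class study conditions are frozen in `baseline_config` /
`progressor_config` (120 nuclei in a 100 µm × 100 µm field at 0.25 µm per
pixel). The progressor class raises lattice jitter (1.0 → 1.15 µm),
lowers orientation concentration (κ 2.0 → 1.6) and widens the axis-ratio
spread (0.05 → 0.057). These deltas were calibrated once so that the
standardized between-class shift of the directly affected features
(Voronoi-area SD, mean co-occurrence entropy, SD of the min/max radius
ratio) is ≈ 1.0 — a realistic effect size for morphometric biomarkers.
Cohorts draw per-patient seeds from a master seed via `SeedSequence`, so
patients are independent and the cohort is bitwise reproducible.

## Segmentation

Stain normalization estimates per-image stain vectors by the
SVD/plane-projection method in optical density (OD = −log10((I+1)/256)):
tissue pixels (total OD > 0.15) are projected onto their two leading
eigenvectors and the 1st/99th-percentile angular extremes are taken as the
hematoxylin and eosin directions; hematoxylin is the vector with the
larger red-channel OD. Concentrations are unmixed by least squares,
scaled so each stain's 99th-percentile ("maximum") concentration matches
the template's, and recomposed with the template's directions. Blank or
single-stain images return unchanged with a warning.

Detection convolves the hematoxylin concentration map with directional
Gaussian second-derivative kernels (negated, so blob centers respond
positively): three scales spanning 2–6 µm equivalent radius × six
orientations, elongation 1.6, response = max over the bank. Seeds are
local maxima above Otsu's threshold (computed on in-ROI response values),
non-maximum-suppressed at half the smallest scale. Segmentation is
marker-controlled watershed on the Sobel gradient of the hematoxylin
channel, with seeds as internal markers and confident background
(hematoxylin below Otsu, dilated away from seeds) as the external marker.
Regions under 8 µm² or touching the image border are dropped; each
surviving region contributes its boundary polygon and polygon centroid.
Coordinates are pixels, origin top-left, x right / y down; microns enter
only through `mpp`. Feature modules accept ground-truth nucleus sets
directly, so feature behavior is testable independent of segmentation
fidelity.

## Feature families (216 features)

The canonical manifest (version 1.0) fixes names, order and family tags;
all modules address features by name.

**Graph (51).** Voronoi tessellation, Delaunay triangulation, Euclidean
MST and k-nearest-neighbor statistics over nuclear centroids, in microns.
Voronoi cells that are unbounded or reach outside the centroid convex hull
are excluded; chord lengths are centroid-to-vertex distances within each
cell. Statistic sets: {mean, SD, min/max ratio, disorder} for
Voronoi/Delaunay/MST quantities (12+8+4), {mean, SD, disorder} for kNN
distances (k ∈ {3,5,7}), neighbor counts within {10..50} µm, and local
density (neighbors within 50 µm per disc area) (27). Disorder is
1 − 1/(1 + SD/mean), a bounded coefficient-of-variation transform that is
0 for perfectly regular arrangements.

**Shape (100).** 25 per-nucleus measures × {mean, median, sample SD,
min/max ratio} over nuclei. Every measure is computed on the contour
resampled to 128 equal-arclength points: area and perimeter; max/mean/SD
of the centroid-to-boundary radial distance; min/max radius ratio;
smoothness (mean local deviation of the radial profile from its neighbor
average, normalized by the mean radius so the measure is scale-free);
box-counting fractal dimension; Hu moments 1–7; Fourier descriptors 1–10
(|Z_k|/|Z_1| of the complex contour, similarity-invariant; descriptor 1 is
1 by construction). Hu moments come from exact polygon moment integrals
(triangle-fan Green's theorem), not rasterization, so rigid-motion
invariance holds to floating point. Fractal dimension is measured in a
canonical frame (centroid at origin, principal axis along x, per-scale
minimum count over the 180° flip) with box coordinates snapped to a 1e-6
grid before flooring — both choices exist solely to make the estimate
pose-independent.

**Orientation disorder (39).** Per-nucleus axial orientation is the first
principal component of the boundary points, folded to [0°, 180°);
near-circular nuclei (covariance eigenvalue ratio < 1.05) are flagged
degenerate with angle 0. Local subgraphs follow a deterministic distance
decay rule — j neighbors i iff d(i,j)^(−α) ≥ threshold, defaults α = 0.5
with a 50 µm equivalent cutoff (the threshold form mirrors the
probabilistic-decay construction in the architecture-feature literature,
made deterministic for reproducibility). Within each non-singleton
subgraph, orientations are quantized into 18 bins of 10° and every
unordered pair increments a symmetric co-occurrence matrix, normalized to
sum 1. Thirteen second-order statistics are computed per subgraph
(contrast energy/inverse moment/average/variance/entropy, intensity
average/variance/entropy, entropy, energy, correlation, and two
information measures of correlation; entropies in bits) and aggregated
across subgraphs by {mean, SD, range}. Contrast-family statistics use the
axial bin distance min(|i−j|, B−|i−j|) — the first and last orientation
bins are adjacent — which makes them exact under field rotations by bin
multiples. Because the matrix is indexed by absolute orientation bins, the
intensity/correlation statistics are not invariant under arbitrary
rotations; invariance of the full feature vector is therefore guaranteed
for rigid motions that preserve axial orientations (translations, 180°
rotations), with only bin-edge effects otherwise.

**Cell cluster graph (26).** Nuclei are merged by single linkage at
eps = 6 µm (only touching/near-touching nuclei merge; larger values would
collapse a packed field into one node), cluster centroids become nodes,
and edges follow the same deterministic decay rule with a 12 µm cutoff —
calibrated once to a mean node degree ≈ 5 on the default synthetic field.
The 26 measures cover counts, degree and edge-length statistics,
eccentricity/diameter/radius/path length on the giant component,
clustering coefficients, component structure, per-node nucleus counts and
the two leading adjacency eigenvalues. An empty graph yields an all-zero
block with a warning.

## Feature identification

The training cohort (30 + 30) is split in stratified halves 30 times. On
each half-A, two 6-feature sets are ranked by ascending two-sided p-value
— Wilcoxon rank-sum and Welch's t-test; ties break by absolute
standardized effect size, then manifest order; constant features get
p = 1 — and each set trains an LDA and a QDA on half-A, scored by AUC on
half-B (4 records/iteration, 120 total). Records with AUC ≥ 0.65 are
retained (per record by default; a per-iteration scope is available) and
the six features recurring most often among retained records win; ties
break by total occurrences over all records, then mean selection rank,
then manifest order. Ranking sees only half-A, so validation labels
cannot leak into selection. The LDA/QDA use an additive ridge
(1e-4 × mean feature variance on the covariance diagonal) so 15-sample
class covariances stay positive definite. The clustergram co-clusters
patients and selected features with average linkage on 1 − Spearman
correlation, z-scoring each feature for display.

## Modeling and evaluation

LDA, QDA and a random forest (100 trees, √p feature subsampling,
unlimited depth, fixed seed) are compared by 100 repetitions of
stratified 3-fold cross-validation (each fold balanced; out-of-fold
scores pooled per repetition for the AUC; accuracy/sensitivity/
specificity at threshold 0.5); the highest mean AUC wins. The operating
point maximizes Youden's J over midpoints of consecutive distinct
training scores, taking the lowest threshold on ties. Held-out evaluation
reports rank-based AUC (ties get half credit), confusion counts at the
operating point, and sensitivity/specificity/PPV/NPV/accuracy — raw
fractions internally, nearest-integer percentages only at the reporting
layer. Progressor is the positive class throughout. Univariate marker
AUCs use the raw measurement as the score; constant measurements return
0.5 with a warning.

## Numerical and design notes

- Sample (n−1) standard deviations everywhere; min/max ratios define the
  all-zero case as 1.
- Degenerate inputs fail loudly (zero-area contours, < 4 or collinear
  centroids, all-singleton subgraphs, single-class labels) except where a
  documented fill is stated (empty cluster graph → zeros + warning).
- Correlation-type co-occurrence statistics are 0 by convention when a
  marginal is degenerate.
- The test suite's end-to-end checks run at desk scale: 120 nuclei per
  patient, 60-patient training and 130-patient held-out cohorts, five
  master seeds — sizes chosen to exercise the full protocol shape
  (15/15 half-splits, 10-per-class folds) at the cohort proportions of
  the emulated study design.
- The learnable stages are exposed as sklearn-style estimators
  (`NucleusFeatureExtractor`, `RepeatedSplitFeatureSelector`,
  `ProgressionClassifier`) so they compose with sklearn pipelines and
  model selection; module-level functions are thin wrappers.

## Limitations

Synthetic fields contain isolated, convex-ish nuclei only; segmentation
scores on them are upper bounds for real tissue. The feature manifest's
within-family decompositions (which statistic accompanies which measure)
follow the architecture-feature literature but are package decisions
frozen in the manifest, as is the indexing/normalization of the Fourier
descriptors. The decay-rule parameters (α, cutoffs, eps) are exposed in
configuration; defaults are calibrated to the synthetic study conditions,
not to any particular tissue.
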