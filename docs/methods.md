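# Methods

## Model

The detector assumes all subjects' overlays are registered to one template
triangle mesh with vertex correspondence (inter-subject surface
registration is upstream and out of scope). At each vertex a control
cohort defines a Gaussian normative model (sample mean, unbiased SD); a
subject is abnormal where its z-score survives a threshold, and isolated
supra-threshold vertices are suppressed by a cluster-extent criterion.
Nothing in the model corrects for covariates (age, sex); abnormality is
purely a deviation from the pooled control distribution.

## Measures

- **Thickness** (mm): mean of the two shortest point-to-surface distances
  between corresponding white and pial vertices. Point-to-surface distance
  is exact point-to-triangle distance minimised over candidate triangles
  selected by a k-d tree over triangle centroids, augmented with all faces
  incident to the few nearest vertices (guards against centroid misses on
  thin or folded geometry).
- **Gray/white contrast** (dimensionless): `(gray − white)/(gray + white)`
  of intensities sampled at ±0.5 mm along the outward vertex normal with
  trilinear interpolation. Samples falling outside the volume are missing
  (NaN). The ratio is invariant to global intensity scaling, so
  non-normalised T1 units are acceptable. With white brighter than gray the
  value lies in (−1, 0); blurring moves it toward 0, so *positive* z means
  more blurring.
- **Mean curvature** (1/mm): cotangent-Laplacian mean-curvature normal with
  mixed Voronoi vertex areas (obtuse corners fall back to area/2 vs
  area/4); sign is positive where the surface is convex outward. On an
  icosphere this reproduces 1/R to ~0.01%.
- Gyrification, sulcal depth and jacobian distance are consumed as
  precomputed overlays only; they depend on inflation/spherical
  registration, which this package does not perform.

Vertex normals are area-weighted averages of incident face normals. Vertex
areas use the barycentric one-third rule (robust on obtuse triangles);
curvature alone uses the mixed Voronoi area its operator requires.

## Smoothing

A smoothing step is `x' = x + dt · M⁻¹ L x`, with `M` the diagonal of
vertex areas and `L` the symmetric zero-row-sum Laplacian with edge weights
`(A_i + A_j)/2`. Because `L` is symmetric with zero row sums, the
area-weighted mean is conserved exactly; `dt` is half the stability limit,
making every update a convex combination of one-ring values (maximum
principle). Missing vertices are removed from the graph and stay missing.

The literature parameterises smoothing by FWHM, not iterations, so the
iteration count for a requested FWHM is calibrated per mesh: a unit impulse
at the vertex nearest the centroid is smoothed step by step, the response
is shell-averaged over geodesic distance, the half-maximum crossing is
located by linear interpolation, and the first iteration count whose
(running-max) measured FWHM brackets the target is chosen by proximity.
Calibration is cached per mesh and raises when the request exceeds the mesh
extent. On a 1 mm grid the measured widths at 5/9/12 mm are within 15% of
target; on meshes whose edge length approaches the requested FWHM the
kernel is resolution-limited and the calibrated width can sit below the
request — coarse meshes cannot distinguish, say, 5 mm from 9 mm kernels.

## Geodesic distance

Dijkstra on the edge graph augmented with two-ring chords (straight-line
lengths between second-ring neighbours). Pure one-ring Dijkstra
overestimates geodesics by up to ~15% depending on direction (metrication
error), which shrank geodesic-disc areas far outside the spherical-cap
closed form; the two-ring augmentation cuts the worst-case inflation to a
few percent while staying deterministic and sparse. Distances remain upper
bounds on the true polyhedral geodesic on convex regions and never fall
below the straight-line distance on a flat patch.

## Detection

- SD floor: 1e−6 × the cohort-wide median SD (fallback 1e−6 when the whole
  cohort is degenerate), so zero-variance vertices cannot yield infinite z.
- Leave-one-out control scoring refits the model per subject (n − 1
  controls); a subject's own values never enter its model.
- Clusters: connected components of the supra-threshold set under one-ring
  edge adjacency, computed per tail so opposite signs never merge
  (`z > z₀` strictly, matching the convention of reporting "z>4").
  Default tail is two-sided — the lesion spectrum includes both thickening
  (dysplasia) and thinning (encephalomalacia) — with the per-cluster sign
  recorded; one-tailed analyses are a flag away.
- Extent correction: a fixed minimum cluster area (default 30 mm²), with an
  optional Monte-Carlo alternative (`cluster_extent_null`) that smooths
  standardized Gaussian noise on the same mesh and returns the 95th
  percentile of the maximal null cluster area. The fixed-area default keeps
  results deterministic and is the one used in the evaluation suite.

## Evaluation

Categorical detection = at least one shared vertex between a cluster and
the lesion label (an optional geodesic adjacency tolerance in mm exists for
onset-zone-style analyses; default 0). Specificity counts control
hemispheres with any cluster, one hemisphere per control overlay.
Area-based metrics weight vertices by surface area: the coverage ratio is
supra-threshold lesion area over lesion area and equals area sensitivity;
area specificity is the correctly classified extra-lesional area. ROC
curves are built from the threshold sweep (one point per threshold, anchors
(0,0) and (1,1), ties in false-positive rate keep the best sensitivity,
trapezoidal AUC) rather than from a continuous score. Percentages are
reported to one decimal, halves rounded away from zero. Electrodes snap to
the nearest vertex (configurable snap limit, default 10 mm), take a
geodesic footprint of radius diameter/2, and are in/on when ≥ 50% of the
footprint area is labelled, adjacent within 10 mm, outside otherwise.

The packaged reference table (13 lesional hemispheres, 11 patients) is a
published worked example for these formulas; its whole-percent figures
(92% union sensitivity, 90% extra-lesional rate) follow the source table's
integer truncation.

## Synthetic cohorts

Each subject overlay is `mean + SD · f` with `f` a unit-variance spatially
correlated Gaussian field: white noise smoothed to a correlation FWHM and
re-standardized per vertex by the smoothing operator's exact per-vertex
output SD (row norms of the dense operator power) on meshes up to 5000
vertices, or a fixed-seed 256-probe Monte-Carlo estimate beyond. Lesions
are geodesic discs with a plateau of `δ` cohort-SDs and a cosine taper over
the outer 20% of the radius, so cluster boundaries are not artificially
crisp; the ground-truth label is the full disc regardless of `δ`. Default
study conditions: icosphere (subdivisions 4, radius 50 mm — the area scale
of a hemisphere's cortex), 41 controls, thickness-like fields (mean 2.5 mm,
SD 0.25 mm, correlation FWHM 15 mm), lesion radius 10 mm, δ = 6 SD.

What the generator does *not* emulate: cortical folding and its curvature/
gyrification structure, registration error, measure-specific spatial
inhomogeneity of the normative SD, inter-measure correlation within
subject, and age effects. Passing tests therefore demonstrate the
statistical machinery (calibration, z-scoring, clustering, metrics) under
the model's own assumptions, not performance on real MRI.

Because leave-one-out z-scores against 40 controls follow a heavier-tailed
t-like distribution, the synthetic control false-positive rate at z > 4
(~10% of hemispheres, two-sided, 2562 vertices) is nonzero even though the
fields are exactly Gaussian; at z > 6 it is essentially zero. The
parameter-recovery study reports both, alongside the ≥ 95% detection rate
of the 6 SD lesion and the null-patient rates.

## Numerical choices and degenerate inputs

- Nearest-vertex ties (voxel projection, k-d tree queries) break to the
  lowest vertex index; cluster ordering is by peak |z| then lowest member
  index — all outputs are deterministic, and every random draw flows from
  one named seed.
- Morphological closing is dilation then erosion by r one-ring steps
  (default r = 1, sized for sub-voxel gaps); it is extensive and idempotent
  at fixed r.
- Label files use set semantics; duplicate or out-of-range indices are
  errors. Empty labels are legal for controls only.
- Surfaces and overlays round-trip through the big-endian binary dialects
  at float32 precision; a plain-text OFF fallback exists for fixtures.

## Problem sizes

The test suite and the acceptance study run on icospheres of 642–10,242
vertices and 41-control cohorts with 40 replicates — sizes chosen so the
full end-to-end suite completes in well under a minute while every rate is
estimated from at least 40 Bernoulli draws (binomial SE ≤ 8 percentage
points) and 1,640 control hemisphere-maps.

## Known limitations

- Dijkstra (even two-ring) geodesics are approximate; electrode footprints
  on coarse meshes may contain a single vertex.
- FWHM calibration assumes an approximately radially symmetric impulse
  response; strongly anisotropic meshes would bias the measured width.
- The ROC is threshold-swept, so AUC depends on the sweep range; no
  statistical comparison between AUCs is provided.
- Real-data thickness/curvature values will not match any specific
  surface-reconstruction pipeline's outputs; the operators here are
  standard discrete-geometry constructions, not re-implementations of one.
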