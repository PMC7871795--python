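# Methods

## Surface operators

All geometry lives on triangle meshes (`TriangleMesh`), validated for
index sanity, edge-manifoldness, consistent orientation and non-degenerate
faces. Two operators underpin everything:

- **Lumped mass** M: diagonal, one third of the incident face areas per
  vertex; sums exactly to the surface area.
- **Cotangent stiffness** S: symmetric positive semi-definite, rows sum
  to zero; open boundaries get the natural (Neumann) treatment. On a flat
  right-triangulated grid the interior stencil reduces to the classical
  5-point umbrella, which the tests assert exactly.

Signed mean curvature is read off the discrete mean-curvature normal,
H_i = −(S X)_i · n_i / (2 A_i) with outward vertex normals, giving the
convention used throughout: **concave (fundus) positive**, convex
negative; a sphere of radius r has H = −1/r. The cotan estimator is
accurate to well under 1% at regular (valence-6) vertices but carries a
known pointwise error of order 15% at the twelve valence-5 vertices of an
icosphere; the tests encode both facts.

Geodesics are Dijkstra shortest paths on the edge graph weighted by
Euclidean edge length — deterministic and accurate to a few percent at
the mesh resolutions used, which is sufficient for thresholding decisions
(exact polyhedral geodesics are out of scope). The **Fiedler length** is
the graph geodesic between the vertices attaining the extrema of the
first nontrivial eigenvector of S x = λ M x (dense generalized
eigensolve below 4000 vertices, shift-inverted Lanczos above); ties are
broken by lowest vertex index. On elongated tubes it recovers the
physical length to within 10%, and it is invariant under vertex
relabeling and rigid motion whenever the extrema are unique — rotationally
symmetric meshes tie entire rings of vertices, so invariance tests use
symmetry-broken fixtures.

## Depth potential function

Depth is the solution of (α M + S) d = M s with s = 2 (H − H̄), H̄ the
area-weighted curvature mean. Subtracting H̄ makes the source integrate
to zero, so d is invariant to constant curvature offsets and has
area-weighted mean zero; the factor 2 follows the original formulation of
the measure. α defaults to **0.03** (the value used by the reference
implementation of the extraction method; the regularization constant
trades local curvature fidelity at large α against global convexity
context at small α). The system is solved by sparse LU; solutions are
linear in the source (asserted to 1e−8) and rigid-motion invariant.

A perfect sphere has constant H, hence zero source and an identically
zero DPF. On a *discrete* sphere the curvature estimate is not exactly
constant, and the residual DPF is set by curvature discretization noise,
about 1–2% of a typical dent-mesh DPF range at subdivision 3 — not by
solver error. `depth_potential_function` therefore accepts an optional
analytic-curvature override, which the tests use to verify the
zero-source ⇒ zero-solution property to machine precision while also
bounding the discrete-curvature residual.

## Filtered watershed

Vertices are flooded in decreasing depth order (ties: lower index first).
A vertex with no labelled neighbour seeds a basin and becomes its pit.
A vertex adjacent to k ≥ 2 basins is a ridge point: the deepest adjacent
basin is the merge target (ties: lower pit index), and every shallower
adjacent basin b merges into it iff R = depth(pit_b) − depth(ridge) < ThR
**and** the graph geodesic between the two current pit vertices is < ThD
(the conjunction is implemented literally). Merged basins keep the deeper
pit; the ridge vertex always joins the target. Geodesic fields are cached
per pit vertex. After flooding, basins with area < ThA are absorbed,
smallest first, into the neighbour sharing the longest boundary (summed
edge length; ties: deeper-pit neighbour, then lower pit index), iterating
to a fixed point. Basins are finally labelled 1..K by decreasing pit
depth.

Every rule above, including all tie-breaks, is replicated independently
in `tests/oracles.py` by a naive implementation (explicit member sets,
networkx geodesics recomputed per merge test); the two agree exactly —
identical partitions and pit vertices — on 50 random bumpy meshes with
random thresholds.

Threshold normalization multiplies ThD by FL/G(FL) and ThA by SA/G(SA);
ThR is a depth quantity and is deliberately not size-normalized. The
group-watershed variant reuses the same machinery on a pit-density map
with (gThR, gThD, gThA) and no subject normalization, restricted to the
support {density > 0}: vertices with zero pit probability carry no
evidence and belong to no cluster. On real-data density maps (hundreds
of subjects, 5 mm smoothing) the support is effectively the whole
surface, so this restriction only matters for sparse synthetic cohorts,
where it prevents the featureless far field from fragmenting into
meaningless clusters.

## Smoothing, projection, density

Pit indicator textures are diffused by the heat equation using explicit
Euler steps of u′ = −M⁻¹ S u. The FWHM is converted to diffusion time by
σ = FWHM/(2√(2 ln 2)), t = σ²/2, split into n_iter = 60 steps; steps
beyond the explicit stability bound (estimated by Gershgorin) are
subdivided automatically with a warning. Negative undershoots are clamped
and the result is rescaled so the global maximum is 1 ("peak kept at
one"; renormalization is global, not per-blob). Against a dense matrix
exponential the smoothed fields agree to within 5%.

Projection to the template is a push through a precomputed total vertex
correspondence, keeping the maximum on collisions (textures are pit
probabilities, so peaks must survive). Spherical or interhemispheric
registration itself is out of scope — correspondences are inputs, and the
identity for synthetic cohorts whose mirrored hemispheres share topology.
The density map is the vertex-wise mean of the subjects' projected
textures; the symmetric parcellation pools both hemispheres of every
subject (2N textures) before the group watershed.

## Classification and counting

Each group cluster receives the across-subject mean of its per-subject
deepest-pit depth (missing subjects excluded; unobserved clusters dropped
with a warning). One-dimensional k-means with k = 3 and 100 random
seeded restarts (best within-class sum of squares; scikit-learn behind
the interface) splits clusters into primary / secondary / dimple by
descending centroid. Recovery of designed three-tier layouts is exact in
at least 99 of 100 seeded runs when the between-tier gap is ≥ 3× the
within-tier spread, and matches an exhaustive contiguous-partition oracle
on the frozen example. Per-subject counts assign each pit, via the
correspondence, to the cluster at its template vertex and that cluster's
class; pits landing outside the parcellation go to a diagnostic
"unassigned" bucket so that class counts + unassigned = total always.

## Statistics

- Group differences: OLS y ~ 1 + group(case=1) + age, two-tailed t on the
  group coefficient; ≥3 subjects per group required. Constant outcomes
  and perfect fits are reported as degenerate (effect 0, p = 1, or p = 0
  for a nonzero forced effect) rather than NaN.
- Age effects: OLS y ~ 1 + age.
- Per-cluster depth tests drop subjects without a pit in that cluster
  (listwise within cluster); clusters with fewer than 3 subjects per
  group are skipped but still count toward the FDR family, implemented by
  padding the Benjamini–Hochberg family to the full parcellation size.
  BH q-values (statsmodels behind the interface) match a hand step-up
  oracle exactly on 1000 random p-vectors.
- Asymmetry: AI = (L − R)/(L + R) on per-cluster deepest-pit depths of
  the symmetric parcellation; undefined when L + R ≤ 0 (pair dropped).
  Group AI differences use the same group+age model per symmetric
  cluster.
- Hemisphere differences within each group: one-within-factor
  repeated-measures ANOVA per symmetric cluster on complete pairs
  (statsmodels AnovaRM), numerically identical to the squared paired t
  (asserted to 1e−10); zero-variance difference vectors are flagged
  degenerate. FDR within each group across symmetric clusters.
- Subtype contrast: same model with a combined-vs-inattentive dummy among
  cases only. IQ is deliberately not a covariate.
- Under the null the group test's type-I error is calibrated: measured
  rejection rate over 2000 simulations lies within [0.035, 0.065] at
  α = 0.05.

## Synthetic cohorts

The generator emulates what the pipeline consumes, not cortex itself:
icospheres (r = 50 mm, subdivision 3, 642 vertices) carrying inward
Gaussian folds displace vertices along normals by
depth·exp(−g²/2w²), g the geodesic distance to the fold-center vertex.
Fold centers come from deterministic farthest-point sampling and must be
pairwise separated by ≥ 3× the largest width (default width 5 mm). The
default layout has 4 primary folds (6 mm, presence 1.0 in both groups —
primary sulci are invariably present), 8 secondary (3.5 mm, presence 0.9
in controls vs 0.7 in cases: the count channel of the group effect) and
4 dimples (1.8 mm, presence 0.85 in both). Per subject and hemisphere,
realized depth is amplitude + per-fold case shift + N(0, 0.4 mm), floored
at 0.1 mm; ages are uniform on 7–14 years and an optional count-age slope
shifts presence probabilities uniformly across folds. Hemispheres are
mirrored copies sharing vertex numbering, so the interhemispheric
correspondence is the identity. Everything is deterministic given the
seed, and the ground truth (presence, depths, pit vertices, tiers) is
returned alongside.

Two consumption channels exist deliberately. The **mesh channel**
(`build_meshes=True`) feeds the full geometric pipeline and is used at
small cohort sizes (6–20 subjects per group) where the end-to-end run
takes seconds. The **tabular channel** exposes the generator's realized
depth tables and counts directly — the exact quantities the pipeline's
cluster tables estimate — and drives the statistical calibration and
recovery studies at n = 60–80 per group over 50+ seeds, where running
the mesh pipeline would add nothing but geometry already validated
separately.

On synthetic spheres the watershed thresholds are
`SYNTHETIC_THRESHOLDS = (ThR 0.5, ThD 1000 mm, ThA 50 mm²)` rather than
the clinical defaults: closed spheres have large featureless regions that
real cortex lacks, whose shallow noise basins (prominence ~0.05 DPF
units) must merge into true basins — so the distance criterion is
disabled (ThD beyond the mesh diameter) and ThR sits between the noise
prominence and the shallowest designed tier's prominence (~1.0 DPF
units). The clinical defaults remain the `PipelineConfig` defaults.

What passing synthetic tests do **not** show: realistic gyral geometry
(real sulci are elongated, branched and crowded, so ridge/distance
filtering operates much closer to its thresholds), registration error
(correspondences here are exact), scanner/site effects, or DPF depth
scales of human cortex (synthetic DPF units are ~0.55 per mm of dent
depth at these fold widths; clinical ThR = 1.5 was calibrated on adult
cortex). Cohort-scale cluster counts (hundreds of clusters) are likewise
not reproduced at 642-vertex resolution.

## Numerical choices and edge cases

- Flooding ties broken by vertex index; all tie-breaks documented above
  and mirrored in the oracle.
- All-equal depth maps yield one basin per component with a warning;
  all-zero densities yield zero clusters with a warning.
- Dijkstra unreachable vertices report +inf; disconnected meshes are
  rejected by the Fiedler computation.
- The explicit smoothing step is auto-subdivided when 60 iterations are
  too few for stability at the given FWHM and mesh.
- GIFTI surfaces are written float32 (round-trip relative error < 1e−6
  at coordinate magnitudes of tens of mm); FreeSurfer binary and GIFTI
  loaders return identical meshes.
- Problem sizes in the test suite (162–2562-vertex meshes, 6–80 subjects
  per group, 50–2000 simulation replicates) were chosen as the smallest
  sizes at which each property is informative; all are package-level
  choices, overridable by the caller.
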