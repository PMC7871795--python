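# sulcalpits

Sulcal pit extraction and group-level morphometry on cortical surface
meshes, with a synthetic folded-surface cohort generator for end-to-end
validation.

Sulcal pits are the locally deepest points of cortical folds. Their
spatial pattern is established early in development and is unusually
stable across life, which makes pit position, count and depth attractive
markers for neurodevelopmental group comparisons (for example children
with ADHD versus typically developing controls). This package implements
the full analysis chain that such studies use:

1. **Depth mapping** — the depth potential function (DPF), a per-vertex
   depth measure obtained by solving the regularized Poisson problem
   (α M + S) d = M s on the white-matter surface, with cotangent stiffness
   S, lumped mass M, and source s = 2(H − H̄) built from mean curvature H.
   Sulcal fundi come out positive, gyral crowns negative.
2. **Pit / basin extraction** — a filtered watershed on the depth map:
   flooding in decreasing depth order, merging two basins at a ridge
   vertex when the ridge height R = (shallower pit depth − ridge depth)
   is below ThR **and** the geodesic inter-pit distance D is below ThD,
   then absorbing basins smaller than ThA into the neighbour sharing the
   longest boundary. ThD and ThA are normalized per subject by the mesh
   Fiedler length FL and surface area SA relative to group means,
   ThD′ = ThD·FL/G(FL), ThA′ = ThA·SA/G(SA), so filtering is independent
   of brain size. Defaults: ThR = 1.5, ThD = 20 mm, ThA = 50 mm²,
   with reference group means G(FL) = 231.8/232.9 mm and
   G(SA) = 91 616/91 980 mm² (left/right).
3. **Group parcellation** — binary pit textures smoothed by heat diffusion
   (FWHM 5 mm in 60 iterations, peak kept at 1), projected to a template
   through precomputed vertex correspondences, and averaged into a pit
   density map; the same watershed (gThR = 2, gThD = 15, gThA = 100)
   divides the density map into group clusters. A symmetric variant pools
   both hemispheres of every subject on one template side.
4. **Sulcal classification** — 1-D k-means (k = 3, 100 replicates) over
   per-cluster mean deepest-pit depth splits clusters into primary sulci,
   secondary sulci and dimples; per-subject pits are counted per class.
5. **Group statistics** — OLS group-difference models with age as
   covariate for pit counts and per-cluster depth, simple age regressions,
   the asymmetry index AI = (L − R)/(L + R) on paired deepest-pit depths
   (+1 fully left-lateralized, −1 fully right), within-group hemisphere
   repeated-measures ANOVA (F = paired t²), and Benjamini–Hochberg FDR
   across the full cluster family.

Because the real inputs are FreeSurfer reconstructions of clinical MRI,
the package ships a **synthetic cohort generator**: spheres carrying
inward Gaussian folds in three depth tiers with group- and age-dependent
presence and depth, mirrored hemispheres sharing topology, and full ground
truth for every subject. Every stage of the pipeline is validated against
this ground truth and against independent oracles (brute-force watershed,
matrix-exponential heat kernels, exhaustive 1-D k-means, step-up FDR).

## Worked example

```python
from sulcalpits import (CohortSpec, PipelineConfig, default_fold_specs,
                        make_cohort, make_sphere, run_pipeline)
from sulcalpits.synthetic import SYNTHETIC_THRESHOLDS

base = make_sphere()                       # r = 50 mm icosphere
spec = CohortSpec(n_case=20, n_control=20,
                  folds=default_fold_specs(base), seed=7)
cohort = make_cohort(spec, build_meshes=True)
result = run_pipeline(cohort, PipelineConfig(thresholds=SYNTHETIC_THRESHOLDS))

print(result.log["cluster_counts"])   # {'left': 16, 'right': 16, 'sym': 16}
print(result.class_map.centroids)     # [3.219 1.88  0.958]
print(result.stats["counts"])
```

The default cohort has 16 folds per hemisphere (4 primary, 8 secondary,
4 dimples) and a built-in group effect: secondary folds are present with
probability 0.9 in controls but 0.7 in cases. The run above recovers one
group cluster per fold, classifies them into the three designed tiers
(depth centroids 3.22 / 1.88 / 0.96 DPF units), and the count statistics
show exactly the injected pattern — a significant secondary-count deficit
in cases (effect −2.77 pits, p < 0.001, against the expected −3.2 =
2 hemispheres × 8 folds × 0.2) carried through to the total count
(−2.37, p < 0.001), with null primary and dimple effects and zero
spuriously significant depth clusters after FDR.

A command-line interface mirrors the library:

```
sulcalpits simulate --out cohort/ --seed 1 --n-case 20 --n-control 20
sulcalpits dpf lh.white --alpha 0.03 --out lh.dpf.shape.gii
sulcalpits extract-pits lh.white --g-fl 231.8 --g-sa 91616 --out-prefix lh
sulcalpits parcellate template.surf.gii tex1.gii tex2.gii --out-prefix group
sulcalpits classify depth_table.csv --out classes.csv
sulcalpits stats records.csv depth_table.csv --out stats.csv
sulcalpits run-all --n-case 10 --n-control 10 --seed 1 --thr 0.5 --out out/
```

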