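"""Synthetic folded-surface cohorts with known ground truth.

Real cohorts of cortical surfaces are replaced by spheres carrying inward
Gaussian "folds" at well-separated locations.  Folds come in three depth
tiers mirroring the primary / secondary / dimple classes; each subject
realizes every fold with a group- and age-dependent presence probability
and a noisy depth, and the two hemispheres are mirrored copies sharing
vertex topology (so the interhemispheric correspondence is the identity).
The generator records the full ground truth — which folds are present,
their realized depths, and the fold-center vertices — so every pipeline
stage can be checked against known answers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh import TriangleMesh, geodesic_distance, vertex_normals
from .watershed import Thresholds

__all__ = [
    "SYNTHETIC_THRESHOLDS",
    "FoldSpec",
    "CohortSpec",
    "Cohort",
    "make_sphere",
    "make_sheet",
    "pick_fold_centers",
    "default_fold_specs",
    "make_folded_surface",
    "make_cohort",
    "ground_truth_depth_table",
    "ground_truth_counts",
    "export_fixtures",
]

TIERS = ("primary", "secondary", "dimple")

#: Watershed thresholds matched to the synthetic depth scale.  The default
#: clinical thresholds target DPF values of adult human cortex; on the
#: synthetic spheres the relevant scales differ in two ways.  First, closed
#: spheres have large featureless regions (no real cortex does), whose
#: shallow watershed seeds must merge into the true basins: the inter-pit
#: distance criterion is disabled (ThD beyond the mesh diameter) so that
#: ridge height alone governs flooding merges.  Second, ThR must sit between
#: the prominence of discretization-noise basins (~0.05 DPF units) and that
#: of the shallowest designed tier (~1.0): 0.5 leaves a comfortable margin
#: on both sides.  ThA keeps its default area.
SYNTHETIC_THRESHOLDS = Thresholds(thr=0.5, thd=1000.0, tha=50.0)

#: Default tier depth amplitudes (mm) and per-group presence probabilities.
#: Primary sulci are invariably present; secondary folds are less often
#: realized in cases (the count channel of the group effect); dimples are
#: inconstant in everyone.
TIER_DEPTH = {"primary": 6.0, "secondary": 3.5, "dimple": 1.8}
TIER_PRESENCE = {
    "primary": {"control": 1.0, "case": 1.0},
    "secondary": {"control": 0.9, "case": 0.7},
    "dimple": {"control": 0.85, "case": 0.85},
}
DEFAULT_TIER_COUNTS = {"primary": 4, "secondary": 8, "dimple": 4}


@dataclass(frozen=True)
class FoldSpec:
    """One fold of the cohort template.

    center : template vertex index of the fold's deepest point.
    depth : inward displacement amplitude at the center, mm.
    width : Gaussian standard deviation of the displacement profile, mm
        (geodesic distance on the base mesh).
    tier : primary / secondary / dimple.
    presence : group -> probability the fold is realized in a subject.
    """

    center: int
    depth: float
    width: float
    tier: str
    presence: dict = field(default_factory=lambda: {"control": 1.0, "case": 1.0})

    def __post_init__(self):
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("fold depth and width must be positive")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass
class CohortSpec:
    """Study conditions for a simulated two-group cohort.

    depth_effects : per-fold case-minus-control shift of realized depth, mm.
    count_age_slope : change in expected total fold count per year of age,
        spread uniformly over the folds' presence probabilities.
    noise_sd : per-subject Gaussian jitter of realized fold depth, mm.
    """

    n_case: int = 20
    n_control: int = 20
    age_range: tuple[float, float] = (7.0, 14.0)
    folds: list[FoldSpec] = field(default_factory=list)
    depth_effects: np.ndarray | None = None
    count_age_slope: float = 0.0
    noise_sd: float = 0.4
    base_subdivisions: int = 3
    base_radius: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one subject per group")
        if self.depth_effects is None:
            self.depth_effects = np.zeros(len(self.folds))
        self.depth_effects = np.asarray(self.depth_effects, dtype=np.float64)
        if len(self.depth_effects) != len(self.folds):
            raise ValueError("depth_effects length must match fold count")


@dataclass
class Cohort:
    """A realized cohort: subject table, ground truth, optional meshes."""

    spec: CohortSpec
    base_mesh: TriangleMesh
    records: pd.DataFrame
    presence: dict  # (subject_id, hemi) -> bool array over folds
    depths: dict  # (subject_id, hemi) -> realized depth (NaN if absent)
    meshes: dict | None = None  # (subject_id, hemi) -> TriangleMesh

    @property
    def fold_specs(self) -> list[FoldSpec]:
        return self.spec.folds

    @property
    def subject_ids(self) -> list[str]:
        return list(self.records["subject_id"])


def make_sphere(subdivisions: int = 3, radius: float = 50.0) -> TriangleMesh:
    """Icosphere base mesh (closed, outward-oriented)."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(
        vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces)
    )


def make_sheet(n: int = 21, spacing: float = 2.0) -> TriangleMesh:
    """Flat square grid patch in the xy-plane with +z normals.

    n x n vertices, `spacing` mm apart; used for dent fixtures where depth
    fields and curvature have closed-form expectations.
    """
    xs = (np.arange(n) - (n - 1) / 2.0) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    faces = []
    for r in range(n - 1):
        for c in range(n - 1):
            a = r * n + c
            b = a + 1
            cc = a + n
            d = cc + 1
            faces.append([a, b, d])
            faces.append([a, d, cc])
    return TriangleMesh(vertices=verts, faces=np.asarray(faces))


def pick_fold_centers(mesh: TriangleMesh, n: int) -> np.ndarray:
    """Deterministic farthest-point sampling of n fold centers.

    Starts at vertex 0 and greedily adds the vertex maximizing the graph
    geodesic distance to the chosen set (ties by lowest index), giving
    well-separated, reproducible fold locations.
    """
    centers = [0]
    dist = geodesic_distance(mesh, [0])
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, geodesic_distance(mesh, [nxt]))
    return np.asarray(centers, dtype=np.int64)


def default_fold_specs(
    mesh: TriangleMesh,
    tier_counts: dict | None = None,
    width: float = 5.0,
) -> list[FoldSpec]:
    """Standard fold layout: farthest-point centers with tiered depths.

    Tiers are interleaved across the sampling order so no tier is
    systematically more clustered than another.
    """
    tier_counts = dict(tier_counts or DEFAULT_TIER_COUNTS)
    n = sum(tier_counts.values())
    centers = pick_fold_centers(mesh, n)
    tier_seq: list[str] = []
    remaining = dict(tier_counts)
    while any(v > 0 for v in remaining.values()):
        for t in TIERS:
            if remaining.get(t, 0) > 0:
                tier_seq.append(t)
                remaining[t] -= 1
    return [
        FoldSpec(
            center=int(c),
            depth=TIER_DEPTH[t],
            width=width,
            tier=t,
            presence=dict(TIER_PRESENCE[t]),
        )
        for c, t in zip(centers, tier_seq)
    ]


def make_folded_surface(
    base: TriangleMesh,
    folds: list[tuple[int, float, float]],
    allow_overlap: bool = False,
) -> tuple[TriangleMesh, np.ndarray]:
    """Displace the base mesh inward to realize folds.

    folds: list of (center_vertex, depth_mm, width_mm).  Each fold moves
    vertices inward along their normals by depth * exp(-g^2 / (2 width^2)),
    g the graph geodesic distance to the center.  Centers must be pairwise
    separated by at least 3x the largest width unless allow_overlap.

    Returns the folded mesh (same topology) and the fold-center vertices,
    which are the ground-truth pits.
    """
    if not folds:
        return (
            TriangleMesh(base.vertices.copy(), base.faces.copy(), base.hemisphere),
            np.empty(0, dtype=np.int64),
        )
    centers = np.array([f[0] for f in folds], dtype=np.int64)
    widths = np.array([f[2] for f in folds])
    if not allow_overlap and len(centers) > 1:
        min_sep = 3.0 * widths.max()
        for i, c in enumerate(centers):
            d = geodesic_distance(base, [c])
            others = np.delete(centers, i)
            if np.any(d[others] < min_sep):
                raise ValueError(
                    f"fold centers closer than 3x max width ({min_sep:.1f} mm); "
                    "pass allow_overlap=True to force"
                )
    normals = vertex_normals(base)
    disp = np.zeros(base.n_vertices)
    for c, depth, width in folds:
        g = geodesic_distance(base, [int(c)])
        disp += depth * np.exp(-(g**2) / (2.0 * width**2))
    verts = base.vertices - normals * disp[:, None]
    return (
        TriangleMesh(verts, base.faces.copy(), base.hemisphere),
        centers,
    )


def _mirror(mesh: TriangleMesh, hemisphere: str = "right") -> TriangleMesh:
    """Mirror across the x=0 plane, reversing faces to keep outward normals."""
    verts = mesh.vertices.copy()
    verts[:, 0] *= -1.0
    faces = mesh.faces[:, [0, 2, 1]].copy()
    return TriangleMesh(verts, faces, hemisphere)


def make_cohort(spec: CohortSpec, build_meshes: bool = False) -> Cohort:
    """Realize a cohort from its spec, fully deterministic given spec.seed.

    Ages are uniform over age_range; fold presence is Bernoulli with the
    fold's group probability adjusted by the age slope; realized depth is
    amplitude + depth_effect (cases only) + N(0, noise_sd), floored at
    0.1 mm.  Hemispheres are drawn independently and realized on mirrored
    copies of the base mesh when build_meshes is set.
    """
    if not spec.folds:
        raise ValueError("cohort spec has no folds")
    rng = np.random.default_rng(spec.seed)
    base = make_sphere(spec.base_subdivisions, spec.base_radius)
    base_left = TriangleMesh(base.vertices.copy(), base.faces.copy(), "left")
    nf = len(spec.folds)
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])

    rows = []
    presence: dict = {}
    depths: dict = {}
    groups = ["case"] * spec.n_case + ["control"] * spec.n_control
    clipped = False
    for i, group in enumerate(groups):
        sid = f"sub-{i:04d}"
        age = float(rng.uniform(*spec.age_range))
        subtype = "none"
        if group == "case":
            subtype = "combined" if rng.uniform() < 0.5 else "inattentive"
        rows.append({"subject_id": sid, "group": group, "age": age,
                     "subtype": subtype})
        for hemi in ("left", "right"):
            pres = np.zeros(nf, dtype=bool)
            dep = np.full(nf, np.nan)
            for f, fold in enumerate(spec.folds):
                p = fold.presence[group] + spec.count_age_slope * (age - mid_age) / nf
                if p < 0 or p > 1:
                    clipped = True
                    p = min(max(p, 0.0), 1.0)
                if rng.uniform() < p:
                    d = fold.depth + rng.normal(0.0, spec.noise_sd)
                    if group == "case":
                        d += spec.depth_effects[f]
                    pres[f] = True
                    dep[f] = max(d, 0.1)
            presence[(sid, hemi)] = pres
            depths[(sid, hemi)] = dep
    if clipped:
        warnings.warn("age-adjusted presence probability clipped to [0, 1]")

    records = pd.DataFrame(rows)
    meshes = None
    if build_meshes:
        meshes = {}
        for sid in records["subject_id"]:
            for hemi in ("left", "right"):
                pres = presence[(sid, hemi)]
                dep = depths[(sid, hemi)]
                realized = [
                    (spec.folds[f].center, float(dep[f]), spec.folds[f].width)
                    for f in range(nf)
                    if pres[f]
                ]
                hemi_base = base_left if hemi == "left" else _mirror(base_left)
                surf, _ = make_folded_surface(hemi_base, realized)
                meshes[(sid, hemi)] = surf
    return Cohort(
        spec=spec,
        base_mesh=base_left,
        records=records,
        presence=presence,
        depths=depths,
        meshes=meshes,
    )


def ground_truth_depth_table(cohort: Cohort, hemisphere: str) -> pd.DataFrame:
    """Subjects x folds table of realized depths (NaN where absent).

    This is the generator's own depth table — the quantity the pipeline's
    ClusterDepthTable estimates — keyed by fold index 1..F.
    """
    sids = cohort.subject_ids
    data = np.vstack([cohort.depths[(sid, hemisphere)] for sid in sids])
    cols = np.arange(1, len(cohort.fold_specs) + 1)
    return pd.DataFrame(data, index=pd.Index(sids, name="subject_id"), columns=cols)


def ground_truth_counts(cohort: Cohort) -> pd.DataFrame:
    """Per-subject true pit counts per tier, summed over both hemispheres."""
    tiers = np.array([f.tier for f in cohort.fold_specs])
    rows = []
    for sid in cohort.subject_ids:
        pres = cohort.presence[(sid, "left")].astype(int) + cohort.presence[
            (sid, "right")
        ].astype(int)
        row = {t: int(pres[tiers == t].sum()) for t in TIERS}
        row["total"] = int(pres.sum())
        row["subject_id"] = sid
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def export_fixtures(cohort: Cohort, directory: str | Path) -> dict:
    """Write the cohort to disk (GIFTI surfaces, CSV tables, JSON truth).

    Returns a manifest mapping relative path -> sha256, itself also written
    as manifest.json.  Requires the cohort to have been built with meshes.
    """
    from .io import write_surface

    if cohort.meshes is None:
        raise ValueError("cohort was built without meshes")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _register(path: Path):
        manifest[str(path.relative_to(directory))] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()

    for (sid, hemi), mesh in sorted(cohort.meshes.items()):
        p = directory / f"{sid}_{hemi}.surf.gii"
        write_surface(mesh, p)
        _register(p)
    p = directory / "records.csv"
    cohort.records.to_csv(p, index=False)
    _register(p)
    # identity correspondence native -> template, one file per hemisphere
    n = cohort.base_mesh.n_vertices
    corr = pd.DataFrame(
        {"source_vertex": np.arange(n), "target_vertex": np.arange(n)}
    )
    for hemi in ("left", "right"):
        p = directory / f"corr_{hemi}.csv"
        corr.to_csv(p, index=False)
        _register(p)
    truth = {
        "folds": [
            {
                "center": f.center,
                "depth": f.depth,
                "width": f.width,
                "tier": f.tier,
                "presence": f.presence,
            }
            for f in cohort.fold_specs
        ],
        "presence": {
            f"{sid}:{hemi}": cohort.presence[(sid, hemi)].astype(int).tolist()
            for sid in cohort.subject_ids
            for hemi in ("left", "right")
        },
        "depths": {
            f"{sid}:{hemi}": [
                None if not np.isfinite(d) else round(float(d), 6)
                for d in cohort.depths[(sid, hemi)]
            ]
            for sid in cohort.subject_ids
            for hemi in ("left", "right")
        },
        "seed": cohort.spec.seed,
    }
    p = directory / "ground_truth.json"
    p.write_text(json.dumps(truth, indent=1, sort_keys=True))
    _register(p)
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
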