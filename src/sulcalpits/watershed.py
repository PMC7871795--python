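"""Filtered watershed extraction of sulcal pits and basins.

Vertices are flooded in order of decreasing depth.  A vertex with no
labelled neighbour seeds a new basin and becomes its pit; a vertex touching
two or more basins is a ridge point, where basins may merge.  Two basins
merge at a ridge when the ridge is shallow relative to the shallower pit
(ridge height R < ThR) AND the two pits are geodesically close (D < ThD).
After flooding, basins smaller than the area threshold ThA are absorbed by
the neighbour sharing the longest boundary.  ThD and ThA are normalized per
subject by Fiedler length and surface area so the filtering is not driven
by brain size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.csgraph as csgraph

from .dpf import DepthMap
from .mesh import TriangleMesh, edge_graph, vertex_areas

__all__ = [
    "Thresholds",
    "NormalizationContext",
    "Basin",
    "PitExtractionResult",
    "normalize_thresholds",
    "extract_pits",
    "pit_indicator_texture",
    "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class Thresholds:
    """Watershed filtering thresholds.

    thr : ridge-height threshold, depth-map units.
    thd : inter-pit geodesic distance threshold, mm.
    tha : minimum basin area, mm^2.
    """

    thr: float = 1.5
    thd: float = 20.0
    tha: float = 50.0

    def __post_init__(self):
        if self.thr < 0 or self.thd < 0 or self.tha < 0:
            raise ValueError("thresholds must be nonnegative")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class NormalizationContext:
    """Subject and group shape descriptors for threshold normalization.

    fl / sa are the subject's Fiedler length (mm) and surface area (mm^2);
    g_fl / g_sa are the group mean values.
    """

    fl: float
    sa: float
    g_fl: float
    g_sa: float

    def __post_init__(self):
        if min(self.fl, self.sa, self.g_fl, self.g_sa) <= 0:
            raise ValueError("normalization context values must be positive")


def normalize_thresholds(defaults: Thresholds, ctx: NormalizationContext) -> Thresholds:
    """Scale ThD by FL/G(FL) and ThA by SA/G(SA); ThR is size-independent."""
    return Thresholds(
        thr=defaults.thr,
        thd=defaults.thd * ctx.fl / ctx.g_fl,
        tha=defaults.tha * ctx.sa / ctx.g_sa,
    )


@dataclass
class Basin:
    """A watershed catchment basin with its sulcal pit.

    pit_depth is the maximum depth over the basin's vertices; area is the
    summed lumped vertex area of its members (mm^2).
    """

    label: int
    vertex_set: np.ndarray  # member vertex indices, sorted
    pit_vertex: int
    pit_depth: float
    area: float


@dataclass
class PitExtractionResult:
    basins: list[Basin]
    vertex_labels: np.ndarray  # per-vertex basin label, 1..K; 0 = unassigned
    thresholds_used: Thresholds
    _pit_vertices: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_basins(self) -> int:
        return len(self.basins)

    @property
    def pit_vertices(self) -> np.ndarray:
        if self._pit_vertices is None:
            self._pit_vertices = np.array(
                [b.pit_vertex for b in self.basins], dtype=np.int64
            )
        return self._pit_vertices


class _BasinForest:
    """Union-find over basins, tracking the current pit of each root.

    A merge always keeps the deeper pit, so roots carry the pit the basin
    would report if flooding stopped now.
    """

    def __init__(self):
        self.parent: list[int] = []
        self.pit_vertex: list[int] = []
        self.pit_depth: list[float] = []

    def make(self, vertex: int, depth: float) -> int:
        idx = len(self.parent)
        self.parent.append(idx)
        self.pit_vertex.append(vertex)
        self.pit_depth.append(depth)
        return idx

    def find(self, b: int) -> int:
        root = b
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[b] != root:
            self.parent[b], b = root, self.parent[b]
        return root

    def union_into(self, child: int, into: int):
        """Merge child's tree into `into`; `into` keeps its pit."""
        self.parent[self.find(child)] = self.find(into)


def _flood(values, th, neighbors, graph, order, basin_of, forest):
    """Flooding pass over `order` (vertex indices in decreasing depth).

    Ties in depth are broken by lower vertex index (stable argsort).  At a
    ridge vertex touching k >= 2 basins, the deepest adjacent basin is the
    merge target (ties by lower pit-vertex index); each shallower basin is
    tested against it with the R/D rule and merged on success; the ridge
    vertex itself always joins the target basin.
    """
    geo_cache: dict[int, np.ndarray] = {}

    def geodesic_from(pit: int) -> np.ndarray:
        if pit not in geo_cache:
            geo_cache[pit] = csgraph.dijkstra(
                graph, directed=False, indices=pit, min_only=True
            )
        return geo_cache[pit]

    for v in order:
        roots = []
        for u in neighbors[v]:
            if basin_of[u] >= 0:
                r = forest.find(basin_of[u])
                if r not in roots:
                    roots.append(r)
        if not roots:
            basin_of[v] = forest.make(int(v), float(values[v]))
            continue
        if len(roots) > 1:
            roots.sort(key=lambda r: (-forest.pit_depth[r], forest.pit_vertex[r]))
            target = roots[0]
            for r in roots[1:]:
                ridge_height = forest.pit_depth[r] - values[v]
                if ridge_height < th.thr:
                    d = geodesic_from(forest.pit_vertex[target])[forest.pit_vertex[r]]
                    if d < th.thd:
                        forest.union_into(r, target)
            basin_of[v] = target
        else:
            basin_of[v] = roots[0]
    for v in order:
        basin_of[v] = forest.find(basin_of[v])


def _boundary_lengths(mesh: TriangleMesh, labels: np.ndarray):
    """Summed edge lengths of the boundary between each pair of basins."""
    G = edge_graph(mesh).tocoo()
    mask = (
        (G.row < G.col)
        & (labels[G.row] >= 0)
        & (labels[G.col] >= 0)
        & (labels[G.row] != labels[G.col])
    )
    out: dict[tuple[int, int], float] = {}
    for i, j, w in zip(G.row[mask], G.col[mask], G.data[mask]):
        a, b = labels[i], labels[j]
        key = (a, b) if a < b else (b, a)
        out[key] = out.get(key, 0.0) + w
    return out


def _merge_small_basins(mesh, basin_of, forest, th):
    """Absorb basins with area < ThA, smallest first (ties by lower pit
    index), each into the neighbour sharing the longest boundary (ties by
    deeper pit, then lower pit index); iterate until stable."""
    va = vertex_areas(mesh)
    dead: set[int] = set()  # isolated sub-ThA basins with no neighbour
    while True:
        roots = [int(r) for r in np.unique(basin_of[basin_of >= 0])]
        if len(roots) <= 1:
            break
        areas = {r: float(va[basin_of == r].sum()) for r in roots}
        small = [r for r in roots if areas[r] < th.tha and r not in dead]
        if not small:
            break
        small.sort(key=lambda r: (areas[r], forest.pit_vertex[r]))
        r = small[0]
        blen = _boundary_lengths(mesh, basin_of)
        nbrs: dict[int, float] = {}
        for (a, b), w in blen.items():
            if a == r:
                nbrs[b] = nbrs.get(b, 0.0) + w
            elif b == r:
                nbrs[a] = nbrs.get(a, 0.0) + w
        if not nbrs:
            dead.add(r)  # disconnected from every other basin: keep as-is
            continue
        best = max(
            nbrs,
            key=lambda q: (nbrs[q], forest.pit_depth[q], -forest.pit_vertex[q]),
        )
        if forest.pit_depth[best] >= forest.pit_depth[r]:
            forest.union_into(r, best)
        else:
            forest.union_into(best, r)
        new_root = forest.find(r)
        basin_of[(basin_of == r) | (basin_of == best)] = new_root
    return basin_of


def extract_pits(
    mesh: TriangleMesh,
    depth: DepthMap | np.ndarray,
    th: Thresholds = DEFAULT_THRESHOLDS,
    support: np.ndarray | None = None,
) -> PitExtractionResult:
    """Run the filtered watershed on a depth map.

    Parameters
    ----------
    mesh : TriangleMesh
    depth : DepthMap or per-vertex array
        Larger values are deeper.
    th : Thresholds
        Already normalized for the subject where applicable.
    support : boolean array, optional
        Restrict flooding to these vertices; the rest stay unassigned
        (label 0).  The group watershed uses this to exclude vertices with
        zero pit probability from the parcellation.

    Returns
    -------
    PitExtractionResult with basins labelled 1..K in order of decreasing
    pit depth (ties by lower pit-vertex index).
    """
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    values = depth.values if isinstance(depth, DepthMap) else np.asarray(depth, float)
    values = mesh.check_field(values)
    if np.ptp(values) == 0:
        warnings.warn("depth map is constant; one basin per component results")

    graph = edge_graph(mesh)
    neighbors = _neighbor_lists(mesh)
    basin_of = np.full(mesh.n_vertices, -1, dtype=np.int64)
    forest = _BasinForest()

    if support is None:
        order = np.argsort(-values, kind="stable")
    else:
        support = np.asarray(support, dtype=bool)
        sub = np.flatnonzero(support)
        if sub.size == 0:
            raise ValueError("empty support mask")
        neighbors = [
            [u for u in neighbors[v] if support[u]] if support[v] else []
            for v in range(mesh.n_vertices)
        ]
        order = sub[np.argsort(-values[sub], kind="stable")]

    _flood(values, th, neighbors, graph, order, basin_of, forest)
    basin_of = _merge_small_basins(mesh, basin_of, forest, th)
    return _finalize(mesh, values, basin_of, th)


def _neighbor_lists(mesh: TriangleMesh) -> list[list[int]]:
    if "neighbor_lists" not in mesh._cache:
        G = edge_graph(mesh)
        indptr, indices = G.indptr, G.indices
        mesh._cache["neighbor_lists"] = [
            indices[indptr[v]: indptr[v + 1]].tolist()
            for v in range(mesh.n_vertices)
        ]
    return mesh._cache["neighbor_lists"]


def _finalize(mesh, values, basin_of, th) -> PitExtractionResult:
    va = vertex_areas(mesh)
    roots = np.unique(basin_of[basin_of >= 0])
    records = []
    for r in roots:
        members = np.flatnonzero(basin_of == r)
        pit = members[np.argmax(values[members])]
        records.append((float(values[pit]), int(pit), members))
    records.sort(key=lambda t: (-t[0], t[1]))
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    basins = []
    for lab, (pit_depth, pit_vertex, members) in enumerate(records, start=1):
        labels[members] = lab
        basins.append(
            Basin(
                label=lab,
                vertex_set=members,
                pit_vertex=pit_vertex,
                pit_depth=pit_depth,
                area=float(va[members].sum()),
            )
        )
    return PitExtractionResult(basins=basins, vertex_labels=labels, thresholds_used=th)


def pit_indicator_texture(result: PitExtractionResult, mesh: TriangleMesh) -> np.ndarray:
    """Binary per-vertex field: 1 at each sulcal pit, 0 elsewhere."""
    tex = np.zeros(mesh.n_vertices)
    for b in result.basins:
        tex[b.pit_vertex] = 1.0
    return tex
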