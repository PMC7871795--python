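"""Group-level parcellation of pit density maps.

Each subject's binary pit texture is smoothed by heat diffusion on the
subject mesh (FWHM-parameterized, peak renormalized to one), projected to a
common template through a precomputed vertex correspondence, and averaged
across subjects into a density map: the probability of finding a pit at
each template location.  The same filtered watershed used for individual
pit extraction then divides the density map into group clusters.  The
symmetric variant pools both hemispheres of every subject onto one template
side so that left and right clusters coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh, laplace_operators, vertex_areas
from .watershed import PitExtractionResult, Thresholds, extract_pits

__all__ = [
    "SmoothingParams",
    "VertexCorrespondence",
    "DensityMap",
    "GroupClusterMap",
    "DEFAULT_GROUP_THRESHOLDS",
    "smooth_texture",
    "project_texture",
    "density_map",
    "group_watershed",
    "build_symmetric_parcellation",
]

#: Group-watershed defaults (gThR in density units, gThD mm, gThA mm^2).
DEFAULT_GROUP_THRESHOLDS = Thresholds(thr=2.0, thd=15.0, tha=100.0)


@dataclass(frozen=True)
class SmoothingParams:
    """Heat-diffusion smoothing: Gaussian FWHM in mm, split into n_iter
    explicit time steps."""

    fwhm: float = 5.0
    n_iter: int = 60

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def total_time(self) -> float:
        """Diffusion time equivalent to a Gaussian of the given FWHM:
        sigma = FWHM / (2 sqrt(2 ln 2)), t = sigma^2 / 2."""
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return 0.5 * sigma**2


@dataclass
class VertexCorrespondence:
    """Total map from source-mesh vertices to template vertices.

    mapping[i] is the template vertex corresponding to source vertex i;
    precomputed externally (identity for synthetic cohorts, spherical
    registration output for real data).
    """

    mapping: np.ndarray
    source_mesh_id: str = ""
    target_mesh_id: str = ""

    def __post_init__(self):
        self.mapping = np.asarray(self.mapping, dtype=np.int64).ravel()
        if self.mapping.size and self.mapping.min() < 0:
            raise ValueError("correspondence contains negative indices")

    @classmethod
    def identity(cls, n: int, mesh_id: str = "") -> "VertexCorrespondence":
        return cls(np.arange(n), mesh_id, mesh_id)


@dataclass
class DensityMap:
    """Vertex-wise pit probability on the template mesh."""

    values: np.ndarray
    n_subjects: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("density values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


@dataclass
class GroupClusterMap:
    """Template-space cluster labels from the group watershed.

    cluster_labels: per-vertex label 1..K; 0 marks vertices outside every
    cluster (zero pit probability).
    """

    cluster_labels: np.ndarray
    n_clusters: int
    template_mesh_id: str = ""
    symmetric: bool = False

    @property
    def labels(self) -> np.ndarray:
        return self.cluster_labels

    def cluster_ids(self) -> np.ndarray:
        return np.arange(1, self.n_clusters + 1)


def smooth_texture(
    mesh: TriangleMesh,
    texture: np.ndarray,
    params: SmoothingParams = SmoothingParams(),
) -> np.ndarray:
    """Diffuse a nonnegative texture on the mesh, keeping the peak at one.

    Explicit Euler steps of the heat equation u' = -M^{-1} S u, with the
    total diffusion time implied by the FWHM divided into n_iter steps.
    Steps exceeding the explicit stability bound are automatically
    subdivided (with a warning).  Negative undershoots are clamped to zero
    and the output is rescaled so its maximum equals 1; an all-zero input
    stays all-zero.
    """
    u = mesh.check_field(texture).copy()
    if np.any(u < 0):
        raise ValueError("texture must be nonnegative")
    if not np.any(u > 0):
        return u
    S, M = laplace_operators(mesh)
    minv = 1.0 / vertex_areas(mesh)
    dt = params.total_time / params.n_iter
    # Gershgorin bound for M^{-1} S: lambda_max <= max_i (S_ii + r_i)/M_i
    diag = S.diagonal()
    absrow = np.abs(S).sum(axis=1).A1 if hasattr(np.abs(S).sum(axis=1), "A1") else np.asarray(np.abs(S).sum(axis=1)).ravel()
    lam_max = float(np.max((diag + (absrow - np.abs(diag))) * minv))
    dt_stable = 2.0 / lam_max
    nsub = 1
    if dt >= 0.9 * dt_stable:
        nsub = int(np.ceil(dt / (0.9 * dt_stable)))
        warnings.warn(
            f"smoothing step {dt:.3g} exceeds stability bound {dt_stable:.3g}; "
            f"subdividing each step into {nsub}"
        )
    h = dt / nsub
    for _ in range(params.n_iter * nsub):
        u = u - h * (minv * (S @ u))
    u = np.clip(u, 0.0, None)
    peak = u.max()
    if peak > 0:
        u = u / peak
    return u


def project_texture(
    texture: np.ndarray,
    corr: VertexCorrespondence,
    target_mesh: TriangleMesh,
) -> np.ndarray:
    """Push a texture through a vertex correspondence onto the template.

    Each source vertex deposits its value at its corresponding template
    vertex; collisions keep the maximum (textures are pit probabilities, so
    max preserves peaks).  Template vertices receiving nothing stay 0.
    """
    texture = np.asarray(texture, dtype=np.float64).ravel()
    if texture.shape[0] != corr.mapping.shape[0]:
        raise ValueError(
            f"texture length {texture.shape[0]} != correspondence length "
            f"{corr.mapping.shape[0]}"
        )
    if corr.mapping.size and corr.mapping.max() >= target_mesh.n_vertices:
        raise ValueError("correspondence maps outside the template mesh")
    out = np.zeros(target_mesh.n_vertices)
    np.maximum.at(out, corr.mapping, texture)
    return out


def density_map(projected_textures: list[np.ndarray]) -> DensityMap:
    """Vertex-wise mean of the subjects' projected pit textures."""
    if len(projected_textures) == 0:
        raise ValueError("need at least one texture")
    arr = np.asarray(projected_textures, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("textures have inconsistent lengths")
    if arr.min() < 0 or arr.max() > 1 + 1e-12:
        raise ValueError("textures must lie in [0, 1]")
    return DensityMap(values=arr.mean(axis=0), n_subjects=arr.shape[0])


def group_watershed(
    template: TriangleMesh,
    density: DensityMap,
    gth: Thresholds = DEFAULT_GROUP_THRESHOLDS,
    symmetric: bool = False,
    template_mesh_id: str = "",
) -> tuple[GroupClusterMap, PitExtractionResult]:
    """Divide the density map into group clusters with the filtered watershed.

    The individual-level flooding/merging machinery is reused verbatim with
    the density as the depth field and (gThR, gThD, gThA) as thresholds —
    no subject normalization.  Vertices with zero density carry no evidence
    of pits and are left outside every cluster (label 0).
    """
    values = template.check_field(density.values)
    support = values > 0
    if not np.any(support):
        warnings.warn("all-zero density map: no clusters")
        labels = np.zeros(template.n_vertices, dtype=np.int64)
        cmap = GroupClusterMap(labels, 0, template_mesh_id, symmetric)
        return cmap, PitExtractionResult([], labels, gth)
    result = extract_pits(template, values, gth, support=support)
    cmap = GroupClusterMap(
        cluster_labels=result.vertex_labels,
        n_clusters=result.n_basins,
        template_mesh_id=template_mesh_id,
        symmetric=symmetric,
    )
    return cmap, result


def build_symmetric_parcellation(
    left_textures: list[np.ndarray],
    right_textures: list[np.ndarray],
    left_corr: list[VertexCorrespondence],
    right_corr: list[VertexCorrespondence],
    template: TriangleMesh,
    gth: Thresholds = DEFAULT_GROUP_THRESHOLDS,
) -> tuple[GroupClusterMap, DensityMap]:
    """Pool both hemispheres of every subject on one template side and
    divide the pooled density with the group watershed.

    Textures must already be smoothed on their native meshes; the
    correspondences map each hemisphere onto the (left) symmetric template.
    """
    if len(left_textures) != len(right_textures):
        raise ValueError("left/right subject counts differ")
    if len(left_corr) != len(left_textures) or len(right_corr) != len(right_textures):
        raise ValueError("missing correspondence for a hemisphere")
    projected = [
        project_texture(t, c, template)
        for t, c in zip(left_textures + right_textures, left_corr + right_corr)
    ]
    dens = density_map(projected)
    cmap, _ = group_watershed(template, dens, gth, symmetric=True)
    return cmap, dens
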