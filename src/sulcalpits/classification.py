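"""Depth-based classification of group clusters into sulcal classes.

Cortical folds split naturally into depth tiers: deep primary sulci that
form early and are present in everyone, shallower secondary sulci, and
"dimples" — shallow, spatially variable indentations.  Here each group
cluster gets the across-subject mean of its deepest-pit depth, and 1-D
k-means (k = 3 by default, best of many seeded restarts) partitions the
clusters into the three classes.  Per-subject pit counts are then tallied
per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .parcellation import GroupClusterMap, VertexCorrespondence
from .watershed import PitExtractionResult

__all__ = [
    "ClassificationParams",
    "SulcalClassMap",
    "CLASS_NAMES",
    "cluster_mean_depth",
    "classify_sulci",
    "count_pits",
]

#: Class names ordered from deepest to shallowest centroid.
CLASS_NAMES = ("primary", "secondary", "dimple")


@dataclass(frozen=True)
class ClassificationParams:
    """k-means settings: k classes, `replicates` seeded restarts."""

    k: int = 3
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SulcalClassMap:
    """Assignment of every classified group cluster to a sulcal class.

    cluster_class maps cluster id -> class name; centroids are the class
    mean depths in descending order (primary first).  With k != 3 the
    classes are named class_1 (deepest) .. class_k.
    """

    cluster_class: dict[int, str]
    centroids: np.ndarray
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    def classes_present(self) -> tuple[str, ...]:
        return self.class_names


def cluster_mean_depth(depth_table: pd.DataFrame) -> pd.Series:
    """Across-subject mean of deepest-pit depth for each group cluster.

    depth_table: subjects x clusters, NaN where a subject has no pit in a
    cluster.  Subjects without a pit are excluded from that cluster's mean;
    clusters observed in no subject are dropped with a warning.
    """
    if depth_table.size == 0:
        raise ValueError("empty depth table")
    means = depth_table.mean(axis=0, skipna=True)
    empty = means.index[means.isna()]
    if len(empty):
        warnings.warn(
            f"{len(empty)} cluster(s) with no observations excluded from "
            f"classification: {list(empty)[:10]}"
        )
    return means.dropna()


def classify_sulci(
    cluster_depths: pd.Series,
    params: ClassificationParams = ClassificationParams(),
) -> SulcalClassMap:
    """1-D k-means over cluster mean depths; deepest class = primary.

    Best of `params.replicates` random restarts by within-class sum of
    squares, deterministic given `params.seed`.
    """
    depths = np.asarray(cluster_depths.values, dtype=np.float64)
    if np.unique(depths).size < params.k:
        raise ValueError(
            f"need >= {params.k} distinct depth values, got {np.unique(depths).size}"
        )
    km = KMeans(
        n_clusters=params.k,
        n_init=params.replicates,
        init="random",
        random_state=params.seed,
    ).fit(depths.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(-centers)  # deepest first
    rank_of = np.empty(params.k, dtype=np.int64)
    rank_of[order] = np.arange(params.k)
    if params.k == 3:
        names = CLASS_NAMES
    else:
        names = tuple(f"class_{i + 1}" for i in range(params.k))
    cluster_class = {
        cid: names[rank_of[lab]]
        for cid, lab in zip(cluster_depths.index, km.labels_)
    }
    return SulcalClassMap(
        cluster_class=cluster_class,
        centroids=centers[order],
        class_names=names,
    )


def count_pits(
    subject_results: dict[str, PitExtractionResult],
    corrs: dict[str, VertexCorrespondence],
    cmap: GroupClusterMap,
    classes: SulcalClassMap,
) -> dict[str, int]:
    """Count one subject's pits per sulcal class, summed over hemispheres.

    Parameters
    ----------
    subject_results : hemisphere -> PitExtractionResult on the native mesh.
    corrs : hemisphere -> correspondence from native mesh to the template
        carrying `cmap`.

    Returns
    -------
    dict with one count per class name, plus "unassigned" (pits landing on
    template vertices outside every cluster, or in clusters excluded from
    classification) and "total" (= sum of all of these).
    """
    counts = {name: 0 for name in classes.class_names}
    counts["unassigned"] = 0
    for hemi, result in subject_results.items():
        corr = corrs[hemi]
        for pit in result.pit_vertices:
            tv = int(corr.mapping[pit])
            label = int(cmap.cluster_labels[tv])
            cls = classes.cluster_class.get(label) if label > 0 else None
            if cls is None:
                counts["unassigned"] += 1
            else:
                counts[cls] += 1
    counts["total"] = sum(counts.values())
    if counts["unassigned"]:
        warnings.warn(
            f"{counts['unassigned']} pit(s) mapped outside the parcellation"
        )
    return counts
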