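"""End-to-end orchestration: depth maps -> pits -> parcellation -> statistics.

`run_pipeline` drives a cohort (real surfaces or a synthetic one) through
every stage in order: DPF depth mapping, subject-normalized pit extraction,
texture smoothing and projection, density maps and group watershed
(asymmetric per hemisphere and symmetric pooled), depth-tier
classification, pit counting, and the full set of group statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .classification import (
    ClassificationParams,
    SulcalClassMap,
    classify_sulci,
    cluster_mean_depth,
    count_pits,
)
from .config import PipelineConfig
from .dpf import depth_potential_function
from .mesh import TriangleMesh, fiedler_length
from .parcellation import (
    DensityMap,
    GroupClusterMap,
    VertexCorrespondence,
    density_map,
    group_watershed,
    project_texture,
    smooth_texture,
)
from .synthetic import Cohort
from .watershed import (
    NormalizationContext,
    PitExtractionResult,
    Thresholds,
    extract_pits,
    normalize_thresholds,
    pit_indicator_texture,
)

__all__ = ["PipelineResult", "run_pipeline", "cluster_depth_table"]

HEMIS = ("left", "right")


@dataclass
class PipelineResult:
    """Bundle of every stage's outputs plus the run log."""

    pit_results: dict  # (subject_id, hemi) -> PitExtractionResult
    shape: pd.DataFrame  # per subject-hemi FL, SA, normalized thresholds
    density: dict  # hemi -> DensityMap; "sym" -> pooled DensityMap
    cluster_maps: dict  # hemi -> GroupClusterMap; "sym" -> symmetric map
    depth_tables: dict  # hemi -> ClusterDepthTable; ("sym", hemi) -> table
    class_map: SulcalClassMap
    counts: pd.DataFrame  # per subject: counts per class + unassigned/total
    stats: dict  # name -> StatResult or DataFrame
    log: dict

    def save(self, directory: str | Path):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(directory / "pit_counts.csv")
        for key, table in self.depth_tables.items():
            name = "_".join(key) if isinstance(key, tuple) else key
            table.to_csv(directory / f"depth_table_{name}.csv")
        for name, obj in self.stats.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(directory / f"stats_{name}.csv")
        cls = pd.DataFrame(
            sorted(self.class_map.cluster_class.items()),
            columns=["cluster", "class"],
        )
        cls.to_csv(directory / "cluster_classes.csv", index=False)
        (directory / "run_log.json").write_text(json.dumps(self.log, indent=1))


def cluster_depth_table(
    pit_results: dict,
    corrs: dict,
    cmap: GroupClusterMap,
    subject_ids: list[str],
    hemi: str,
) -> pd.DataFrame:
    """Subjects x clusters table of deepest-pit depth for one hemisphere.

    A cell is present only if the subject has at least one pit projecting
    into that cluster; with several pits the deepest one's depth is used.
    """
    cols = cmap.cluster_ids()
    data = np.full((len(subject_ids), len(cols)), np.nan)
    for si, sid in enumerate(subject_ids):
        result: PitExtractionResult = pit_results[(sid, hemi)]
        corr: VertexCorrespondence = corrs[(sid, hemi)]
        for basin in result.basins:
            label = int(cmap.cluster_labels[int(corr.mapping[basin.pit_vertex])])
            if label > 0:
                j = label - 1
                if np.isnan(data[si, j]) or basin.pit_depth > data[si, j]:
                    data[si, j] = basin.pit_depth
    return pd.DataFrame(
        data, index=pd.Index(subject_ids, name="subject_id"), columns=cols
    )


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a cohort built with meshes.

    Threshold normalization uses config.group_means when given (e.g. the
    healthy-adult reference values); otherwise the cohort's own
    per-hemisphere mean Fiedler length and surface area — the natural
    choice when the analyzed cohort is itself the reference group.
    """
    config = config or PipelineConfig()
    if cohort.meshes is None:
        raise ValueError("cohort must be built with build_meshes=True")
    sids = cohort.subject_ids
    template = cohort.base_mesh
    log: dict = {
        "config": {
            "thresholds": vars(config.thresholds),
            "group_thresholds": vars(config.group_thresholds),
            "smoothing": {"fwhm": config.smoothing.fwhm,
                          "n_iter": config.smoothing.n_iter},
            "dpf_alpha": config.dpf_alpha,
            "k": config.classification.k,
            "replicates": config.classification.replicates,
            "alpha_level": config.alpha_level,
            "seed": config.seed,
        },
        "stages": [],
    }

    # --- per-subject depth maps and shape descriptors -------------------
    depth_maps = {}
    shape_rows = []
    for sid in sids:
        for hemi in HEMIS:
            mesh = cohort.meshes[(sid, hemi)]
            depth_maps[(sid, hemi)] = depth_potential_function(mesh, config.dpf_alpha)
            sd = fiedler_length(mesh)
            shape_rows.append(
                {"subject_id": sid, "hemisphere": hemi,
                 "fl": sd.fiedler_length, "sa": sd.surface_area}
            )
    shape = pd.DataFrame(shape_rows)
    log["stages"].append("dpf")

    # --- subject-normalized pit extraction ------------------------------
    group_means = {}
    for hemi in HEMIS:
        sub = shape[shape["hemisphere"] == hemi]
        if config.group_means is not None:
            group_means[hemi] = config.group_means[hemi]
        else:
            group_means[hemi] = {"fl": float(sub["fl"].mean()),
                                 "sa": float(sub["sa"].mean())}
    pit_results = {}
    norm_cols = {"thr": [], "thd": [], "tha": []}
    for row in shape.itertuples():
        ctx = NormalizationContext(
            fl=row.fl, sa=row.sa,
            g_fl=group_means[row.hemisphere]["fl"],
            g_sa=group_means[row.hemisphere]["sa"],
        )
        th = normalize_thresholds(config.thresholds, ctx)
        for k in norm_cols:
            norm_cols[k].append(getattr(th, k))
        key = (row.subject_id, row.hemisphere)
        pit_results[key] = extract_pits(cohort.meshes[key], depth_maps[key], th)
    for k, v in norm_cols.items():
        shape[f"norm_{k}"] = v
    log["stages"].append("extract_pits")
    log["normalized_thresholds"] = shape[
        ["subject_id", "hemisphere", "norm_thr", "norm_thd", "norm_tha"]
    ].to_dict(orient="records")

    # --- smoothing, projection, densities -------------------------------
    corrs = {
        (sid, hemi): VertexCorrespondence.identity(template.n_vertices)
        for sid in sids for hemi in HEMIS
    }
    smoothed = {}
    projected = {hemi: [] for hemi in HEMIS}
    for sid in sids:
        for hemi in HEMIS:
            mesh = cohort.meshes[(sid, hemi)]
            tex = pit_indicator_texture(pit_results[(sid, hemi)], mesh)
            s = smooth_texture(mesh, tex, config.smoothing)
            smoothed[(sid, hemi)] = s
            projected[hemi].append(project_texture(s, corrs[(sid, hemi)], template))
    density = {hemi: density_map(projected[hemi]) for hemi in HEMIS}
    density["sym"] = density_map(projected["left"] + projected["right"])
    log["stages"].append("density")

    # --- group watersheds -----------------------------------------------
    cluster_maps = {}
    for hemi in HEMIS:
        cluster_maps[hemi], _ = group_watershed(
            template, density[hemi], config.group_thresholds,
            template_mesh_id=f"template_{hemi}",
        )
    cluster_maps["sym"], _ = group_watershed(
        template, density["sym"], config.group_thresholds,
        symmetric=True, template_mesh_id="template_sym",
    )
    log["stages"].append("group_watershed")
    log["cluster_counts"] = {k: int(v.n_clusters) for k, v in cluster_maps.items()}

    # --- depth tables -----------------------------------------------------
    depth_tables: dict = {}
    for hemi in HEMIS:
        depth_tables[hemi] = cluster_depth_table(
            pit_results, corrs, cluster_maps[hemi], sids, hemi
        )
    for hemi in HEMIS:
        depth_tables[("sym", hemi)] = cluster_depth_table(
            pit_results, corrs, cluster_maps["sym"], sids, hemi
        )

    # --- classification and counts ---------------------------------------
    # one depth-tier classification across both hemispheres' cluster maps,
    # on the concatenated per-cluster mean depths
    mean_left = cluster_mean_depth(depth_tables["left"]).rename(
        lambda c: f"left:{c}"
    )
    mean_right = cluster_mean_depth(depth_tables["right"]).rename(
        lambda c: f"right:{c}"
    )
    class_map = classify_sulci(
        pd.concat([mean_left, mean_right]), config.classification
    )
    per_hemi_class = {
        hemi: SulcalClassMap(
            cluster_class={
                int(k.split(":")[1]): v
                for k, v in class_map.cluster_class.items()
                if str(k).startswith(f"{hemi}:")
            },
            centroids=class_map.centroids,
            class_names=class_map.class_names,
        )
        for hemi in HEMIS
    }
    count_rows = []
    for sid in sids:
        row: dict = {"subject_id": sid}
        for name in (*class_map.class_names, "unassigned", "total"):
            row[name] = 0
        for hemi in HEMIS:
            c = count_pits(
                {hemi: pit_results[(sid, hemi)]},
                {hemi: corrs[(sid, hemi)]},
                cluster_maps[hemi],
                per_hemi_class[hemi],
            )
            for k, v in c.items():
                row[k] += v
        count_rows.append(row)
    counts = pd.DataFrame(count_rows).set_index("subject_id")
    log["stages"].append("classification")

    # --- statistics -------------------------------------------------------
    records = cohort.records.set_index("subject_id").loc[sids].reset_index()
    results: dict = {}
    count_stats = []
    for name in (*class_map.class_names, "total"):
        g = st.group_age_regression(counts[name].to_numpy(), records)
        a = st.age_regression(counts[name].to_numpy(), records)
        count_stats.append(
            {"measure": name, "group_effect": g.effect, "group_t": g.statistic,
             "group_p": g.p_value, "age_slope": a.effect, "age_p": a.p_value,
             "n": g.n_used}
        )
    results["counts"] = pd.DataFrame(count_stats).set_index("measure")

    family_asym = sum(cluster_maps[h].n_clusters for h in HEMIS)
    depth_joint = pd.concat(
        [
            depth_tables["left"].rename(columns=lambda c: f"left:{c}"),
            depth_tables["right"].rename(columns=lambda c: f"right:{c}"),
        ],
        axis=1,
    )
    results["depth"] = st.per_cluster_tests(depth_joint, records, family_asym)

    n_sym = cluster_maps["sym"].n_clusters
    results["ai"] = st.ai_group_tests(
        depth_tables[("sym", "left")], depth_tables[("sym", "right")],
        records, n_sym,
    )
    for grp in ("control", "case"):
        results[f"hemi_{grp}"] = st.within_group_hemisphere_test(
            depth_tables[("sym", "left")], depth_tables[("sym", "right")],
            records, grp, n_sym,
        )
    try:
        results["subtype_total_count"] = st.subtype_comparison(
            counts["total"].to_numpy(), records
        )
    except ValueError:
        results["subtype_total_count"] = None
    log["stages"].append("stats")

    return PipelineResult(
        pit_results=pit_results,
        shape=shape,
        density=density,
        cluster_maps=cluster_maps,
        depth_tables=depth_tables,
        class_map=class_map,
        counts=counts,
        stats=results,
        log=log,
    )
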