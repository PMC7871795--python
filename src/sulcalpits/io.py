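"""Surface and per-vertex field I/O (FreeSurfer and GIFTI), via nibabel.

Vertex indexing is 0-based everywhere internally; format detection is by
extension (.gii -> GIFTI, anything else -> FreeSurfer binary).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import nibabel as nib
import pandas as pd

from .mesh import TriangleMesh
from .parcellation import VertexCorrespondence

__all__ = [
    "read_surface",
    "write_surface",
    "read_scalar",
    "write_scalar",
    "read_correspondence",
    "write_correspondence",
]


def _is_gifti(path: Path, fmt: str | None) -> bool:
    if fmt is not None:
        if fmt not in ("freesurfer", "gifti"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt == "gifti"
    return path.suffix == ".gii"


def read_surface(path: str | Path, fmt: str | None = None,
                 hemisphere: str = "none") -> TriangleMesh:
    """Load a triangle mesh from GIFTI .surf.gii or FreeSurfer binary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if _is_gifti(path, fmt):
            img = nib.load(str(path))
            coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
            tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
            if not coords or not tris:
                raise ValueError("GIFTI file lacks pointset/triangle arrays")
            vertices = coords[0].data
            faces = tris[0].data
        else:
            vertices, faces = nib.freesurfer.read_geometry(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse surface {path}: {exc}") from exc
    return TriangleMesh(np.asarray(vertices, dtype=np.float64),
                        np.asarray(faces, dtype=np.int64), hemisphere)


def write_surface(mesh: TriangleMesh, path: str | Path, fmt: str | None = None):
    path = Path(path)
    if _is_gifti(path, fmt):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32),
                    intent="NIFTI_INTENT_POINTSET",
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    else:
        nib.freesurfer.write_geometry(str(path), mesh.vertices, mesh.faces)


def read_scalar(path: str | Path, fmt: str | None = None) -> np.ndarray:
    """Load a per-vertex scalar field (.shape.gii or FreeSurfer morph)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if _is_gifti(path, fmt):
            img = nib.load(str(path))
            if not img.darrays:
                raise ValueError("GIFTI file has no data arrays")
            return np.asarray(img.darrays[0].data, dtype=np.float64)
        return np.asarray(nib.freesurfer.read_morph_data(str(path)),
                          dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"cannot parse scalar field {path}: {exc}") from exc


def write_scalar(values: np.ndarray, path: str | Path, fmt: str | None = None):
    values = np.asarray(values)
    path = Path(path)
    if _is_gifti(path, fmt):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    values.astype(np.float32), intent="NIFTI_INTENT_SHAPE"
                )
            ]
        )
        nib.save(img, str(path))
    else:
        nib.freesurfer.write_morph_data(str(path), values)


def read_correspondence(path: str | Path) -> VertexCorrespondence:
    """Load a vertex correspondence CSV (source_vertex, target_vertex)."""
    df = pd.read_csv(path)
    for col in ("source_vertex", "target_vertex"):
        if col not in df.columns:
            raise ValueError(f"correspondence CSV missing column {col!r}")
    df = df.sort_values("source_vertex")
    src = df["source_vertex"].to_numpy()
    if not np.array_equal(src, np.arange(len(src))):
        raise ValueError("correspondence must cover every source vertex exactly once")
    return VertexCorrespondence(df["target_vertex"].to_numpy())


def write_correspondence(corr: VertexCorrespondence, path: str | Path):
    pd.DataFrame(
        {
            "source_vertex": np.arange(len(corr.mapping)),
            "target_vertex": corr.mapping,
        }
    ).to_csv(path, index=False)
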