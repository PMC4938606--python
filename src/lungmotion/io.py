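"""Mesh / feature-table input-output helpers.

Labeled meshes are written as PLY (or STL) with one face color per
anatomical label (the color convention used by the supplementary lung
meshes of dynamic-MRI studies: per-triangle color encodes the surface
part); feature tables and curves go to CSV, partition reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import partition as pt
from .meshcore import SurfaceMesh

# label → RGBA face color (costal parts blues/greens, medial yellow, diaphragm red)
LABEL_COLORS = {
    pt.COSTAL_ANTERIOR: (70, 130, 180, 255),
    pt.COSTAL_POSTERIOR: (46, 139, 87, 255),
    pt.COSTAL_SUPERIOR: (135, 206, 250, 255),
    pt.COSTAL_LATERAL: (60, 179, 113, 255),
    pt.MEDIAL: (240, 200, 60, 255),
    pt.DIAPHRAGMATIC: (200, 60, 60, 255),
}
_COLOR_TO_LABEL = {v[:3]: k for k, v in LABEL_COLORS.items()}


def write_labeled_mesh(partition: pt.SurfacePartition, path) -> None:
    """Write mesh + per-triangle label colors as PLY/STL (by extension)."""
    mesh = trimesh.Trimesh(vertices=partition.mesh.vertices,
                           faces=partition.mesh.faces, process=False)
    colors = np.array([LABEL_COLORS[int(l)] for l in partition.labels], dtype=np.uint8)
    mesh.visual.face_colors = colors
    mesh.export(str(path))


def read_labeled_mesh(path) -> pt.SurfacePartition:
    """Read a labeled PLY/STL written by :func:`write_labeled_mesh`."""
    mesh = trimesh.load(str(path), force="mesh", process=False)
    colors = np.asarray(mesh.visual.face_colors)[:, :3]
    labels = np.array([_COLOR_TO_LABEL.get(tuple(c), pt.COSTAL_LATERAL)
                       for c in colors])
    return pt.SurfacePartition(labels, SurfaceMesh(mesh.vertices, mesh.faces))


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")


def features_to_frame(features: dict, subject: str = "subject",
                      lung: str = "right") -> pd.DataFrame:
    row = {"subject": subject, "lung": lung}
    row.update({k: features[k] for k in sorted(features)})
    return pd.DataFrame([row])


def curves_to_frame(curves: dict) -> pd.DataFrame:
    """Time curves (V, CC, AP, orientation) as a tidy frame, one row per frame."""
    usable = {k: np.asarray(v) for k, v in curves.items()
              if np.asarray(v).ndim == 1 and len(np.asarray(v)) > 2}
    T = max(len(v) for v in usable.values())
    out = {"t": np.arange(1, T + 1)}
    for k, v in usable.items():
        if len(v) == T:
            out[k] = v
    return pd.DataFrame(out)
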