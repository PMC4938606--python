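"""2D unfolded-box excursion maps of the lung surface.

Each labeled surface part is associated with a side of a rectangular box
(diaphragm → bottom; anterior/posterior/lateral costal → front/back/left/
right), orthographically projected onto its box face and rotated about the
shared bottom edge into the bottom plane.  Superior costal triangles are not
part of the map.  The module emits backend-neutral (u, v, value) triangle
records; any plotting layer may rasterize them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import partition as pt
from .kinematics import TrackedMesh
from .partition import SurfacePartition

# map segments; lateral costal is split by the sign of the face normal's x
SEGMENTS = ("bottom", "front", "back", "left", "right")


@dataclass
class UnfoldedMap:
    """Planar embedding of the labeled surface with per-triangle values."""

    table: pd.DataFrame  # columns: segment, triangle, u, v, excursion_mm

    def segment(self, name: str) -> pd.DataFrame:
        return self.table[self.table.segment == name]


def _segment_of(labels: np.ndarray, normals: np.ndarray) -> np.ndarray:
    seg = np.full(len(labels), "", dtype=object)
    seg[labels == pt.DIAPHRAGMATIC] = "bottom"
    seg[labels == pt.COSTAL_ANTERIOR] = "front"
    seg[labels == pt.COSTAL_POSTERIOR] = "back"
    lat = labels == pt.COSTAL_LATERAL
    seg[lat & (normals[:, 0] < 0)] = "left"
    seg[lat & (normals[:, 0] >= 0)] = "right"
    return seg


def unfold_surface(mesh, partition: SurfacePartition) -> pd.DataFrame:
    """Planar (u, v) coordinates per mapped triangle centroid.

    The bottom face keeps (x, y); each side is orthographically projected
    onto its box face and hinged about the bottom edge it shares with the
    bottom rectangle, so segments tile the plane around the bottom without
    overlapping.
    """
    lo, hi = mesh.bounds
    c = mesh.triangles_center
    seg = _segment_of(partition.labels, mesh.face_normals)
    rows = []
    for t in range(len(c)):
        s = seg[t]
        if not s:
            continue
        x, y, z = c[t]
        if s == "bottom":
            u, v = x, y
        elif s == "front":      # +y face, hinge at y = hi[1]
            u, v = x, hi[1] + (z - lo[2])
        elif s == "back":       # −y face, hinge at y = lo[1]
            u, v = x, lo[1] - (z - lo[2])
        elif s == "right":      # +x face, hinge at x = hi[0]
            u, v = hi[0] + (z - lo[2]), y
        else:                   # left, −x face, hinge at x = lo[0]
            u, v = lo[0] - (z - lo[2]), y
        rows.append((s, t, u, v))
    return pd.DataFrame(rows, columns=["segment", "triangle", "u", "v"])


def excursion_map(tracked: TrackedMesh, partition: SurfacePartition) -> UnfoldedMap:
    """Per-triangle maximum excursion (mm, relative to frame 1) along each
    segment's axis, with inward motion positive:

    lateral → LR toward the mid-sagittal plane; anterior/posterior → AP
    toward the mid-coronal plane; diaphragm → CC cranial.
    """
    geo = unfold_surface(tracked.mesh, partition)
    lo, hi = tracked.mesh.bounds
    c1 = tracked.centroids(1)
    tri = geo.triangle.to_numpy()
    disp = np.stack([tracked.centroids(t)[tri] - c1[tri]
                     for t in range(1, tracked.T + 1)])  # (T, n, 3)
    seg = geo.segment.to_numpy()
    axis = np.where(seg == "bottom", 2, np.where(np.isin(seg, ("front", "back")), 1, 0))
    sign = np.ones(len(tri))
    sign[seg == "front"] = -1.0   # anterior moving toward mid-coronal = −y
    sign[seg == "right"] = -1.0   # +x side moving toward mid-sagittal = −x
    comp = disp[:, np.arange(len(tri)), axis] * sign  # (T, n)
    idx = np.argmax(np.abs(comp), axis=0)
    value = comp[idx, np.arange(comp.shape[1])]
    out = geo.copy()
    out["excursion_mm"] = value
    return UnfoldedMap(out)
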