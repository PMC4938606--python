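"""Motion and geometry features of a tracked lung surface.

The reference mesh (full expiration, frame T) is propagated through all T
frames with a displacement provider; features are computed per lung:

Basic (single-frame geometry over time):
  B1 residual volume V(T); B2 vital capacity V(1)−V(T); B3 volume ratio;
  B4/B5 cranio-caudal / antero-posterior size ratios (inspiration vs
  expiration); B6 = B4/B5.  Plus the V(t), CC(t), AP(t) curves.

Advanced (motion attribution):
  A1/A2 volumes displaced by the diaphragmatic / costal surface (swept
  triangle volumes, regions eroded by two triangle strips); A3 diaphragm
  contribution; A4 mean cranio-caudal diaphragm excursion; A5 posterior −
  anterior excursion contrast (right lung); A6/A7 diaphragm dome
  orientation at full inspiration and its largest signed change during the
  maneuver.

Sign conventions: swept volume is positive for inward motion (expiration
displaces volume out of the lung); excursion is cranial-positive relative
to full inspiration; orientation is the area-weighted sagittal-plane angle
between the dome's outward (caudal) normal and the −z axis, positive for a
backwards-tilted (posterior-low) dome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .meshcore import SurfaceMesh, erode_region, triangle_adjacency
from .partition import SurfacePartition


@dataclass
class TrackedMesh:
    """One mesh connectivity with vertex positions at every frame t ∈ [1..T].

    ``positions[t-1]`` are the vertex coordinates at frame t; the reference
    (frame T, full expiration) equals the extraction mesh.
    """

    mesh: SurfaceMesh                 # reference connectivity + positions
    positions: np.ndarray             # (T, N, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (T, N, 3)")
        if self.positions.shape[1] != len(self.mesh.vertices):
            raise ValueError("vertex count mismatch with reference mesh")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least 2 frames")

    @property
    def T(self) -> int:
        return self.positions.shape[0]

    def frame_triangles(self, t: int) -> np.ndarray:
        """(M, 3, 3) triangle vertex coordinates at 1-based frame t."""
        return self.positions[t - 1][self.mesh.faces]

    def frame_volume(self, t: int) -> float:
        tri = self.frame_triangles(t)
        return float(np.einsum("ij,ij->i", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def centroids(self, t: int) -> np.ndarray:
        return self.frame_triangles(t).mean(axis=1)


def propagate_mesh(reference: SurfaceMesh,
                   field: Callable[[np.ndarray, int], np.ndarray],
                   T: int) -> TrackedMesh:
    """Propagate the reference (frame-T) mesh to all frames with a
    displacement provider ``field(points, t) -> positions`` (t 1-based;
    must be the identity at t = T)."""
    if T < 2:
        raise ValueError("T must be >= 2")
    ref = np.asarray(reference.vertices, float)
    positions = np.empty((T, len(ref), 3))
    for t in range(1, T + 1):
        pos = np.asarray(field(ref, t), float)
        if pos.shape != ref.shape:
            raise ValueError(f"displacement provider returned bad shape at t={t}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"displacement provider returned non-finite positions at t={t}")
        positions[t - 1] = pos
    tracked = TrackedMesh(reference, positions)
    for t in range(1, T + 1):
        if tracked.frame_volume(t) <= 0:
            warnings.warn(f"flipped (non-positive volume) frame at t={t}", stacklevel=2)
    return tracked


# ---------------------------------------------------------------------------
# Swept volumes
# ---------------------------------------------------------------------------

def swept_volumes_step(tracked: TrackedMesh, t: int,
                       triangles: Optional[np.ndarray] = None) -> np.ndarray:
    """Signed volume swept by each triangle between frames t and t+1
    (positive when the triangle moves against its outward normal, i.e.
    inward — expiration-positive).

    The swept region is the closed prism joining the triangle at t and at
    t+1 (two caps + three side quads, consistently oriented).  Each side
    quad is split along the diagonal attached to the smaller *global* vertex
    id, so the side surfaces of prisms sharing a mesh edge are identical
    with opposite orientation and cancel exactly — the sum over a closed
    surface telescopes to V(t) − V(t+1) to rounding error.
    """
    faces = tracked.mesh.faces
    A = tracked.positions[t - 1][faces]
    B = tracked.positions[t][faces]
    if triangles is not None:
        sel = np.asarray(triangles, int)
        faces, A, B = faces[sel], A[sel], B[sel]

    def vol(p, q, r):
        return np.einsum("ij,ij->i", p, np.cross(q, r))

    # caps: bottom (at t) reversed, top (at t+1) as wound
    total = vol(A[:, 0], A[:, 2], A[:, 1]) + vol(B[:, 0], B[:, 1], B[:, 2])
    for e0, e1 in ((0, 1), (1, 2), (2, 0)):
        ai, aj = A[:, e0], A[:, e1]
        bi, bj = B[:, e0], B[:, e1]
        lower_first = faces[:, e0] < faces[:, e1]
        # quad (ai, aj, bj, bi): diagonal ai-bj or aj-bi by global vertex id
        diag_a = vol(ai, aj, bj) + vol(ai, bj, bi)
        diag_b = vol(ai, aj, bi) + vol(aj, bj, bi)
        total = total + np.where(lower_first, diag_a, diag_b)
    # 'total' is V(t+1)-like minus V(t)-like: negate for inward-positive
    return -total / 6.0


@dataclass
class FeatureTable:
    """Per-lung scalar features and time curves."""

    features: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return dict(self.features)


def basic_features(tracked: TrackedMesh, partition: SurfacePartition) -> FeatureTable:
    """Volume and size features B1–B6 plus the V(t), CC(t), AP(t) curves.

    CC size = z(lung apex) − z(diaphragm apex), both recomputed per frame
    (the diaphragm apex is the highest vertex of the diaphragmatic surface,
    labels transported by connectivity); AP size = AP extent of the whole
    lung.  Volumes in liters, sizes in mm.
    """
    T = tracked.T
    V = np.array([tracked.frame_volume(t) for t in range(1, T + 1)])
    dia = partition.diaphragmatic
    d_vertices = np.unique(tracked.mesh.faces[dia]) if len(dia) else np.empty(0, int)

    CC = np.full(T, np.nan)
    AP = np.empty(T)
    for t in range(1, T + 1):
        pos = tracked.positions[t - 1]
        AP[t - 1] = pos[:, 1].max() - pos[:, 1].min()
        if len(d_vertices):
            CC[t - 1] = pos[:, 2].max() - pos[d_vertices, 2].max()

    feats = {
        "B1": V[-1] * 1e-6,
        "B2": (V[0] - V[-1]) * 1e-6,
        "B3": V[0] / V[-1],
        "B5": AP[0] / AP[-1],
    }
    if len(d_vertices):
        feats["B4"] = CC[0] / CC[-1]
        feats["B6"] = feats["B4"] / feats["B5"]
    else:
        warnings.warn("empty diaphragmatic region: B4/B6 undefined", stacklevel=2)
        feats["B4"] = feats["B6"] = float("nan")
    curves = {"V_mm3": V, "CC_mm": CC, "AP_mm": AP}
    return FeatureTable(feats, curves)


def swept_volume_features(tracked: TrackedMesh, partition: SurfacePartition,
                          erosion_strips: int = 2) -> FeatureTable:
    """Displaced-volume features A1–A3 (regions eroded by two triangle
    strips to drop unreliable boundary measurements) and the per-step
    ΔV_D(t), ΔV_C(t) curves.  A1/A2 in liters (RV-normalized variants are
    also emitted as A1_rv/A2_rv); A3 is the diaphragm fraction."""
    adjacency = triangle_adjacency(tracked.mesh)
    regions = {}
    for name, tris in (("D", partition.diaphragmatic), ("C", partition.costal)):
        if len(tris) == 0:
            regions[name] = np.empty(0, int)
            continue
        regions[name] = erode_region(tris, adjacency, strips=erosion_strips)

    T = tracked.T
    dvd = np.zeros(T - 1)
    dvc = np.zeros(T - 1)
    for t in range(1, T):
        if len(regions["D"]):
            dvd[t - 1] = swept_volumes_step(tracked, t, regions["D"]).sum()
        if len(regions["C"]):
            dvc[t - 1] = swept_volumes_step(tracked, t, regions["C"]).sum()

    rv = tracked.frame_volume(T) * 1e-6
    a1, a2 = dvd.sum() * 1e-6, dvc.sum() * 1e-6
    denom = a1 + a2
    feats = {
        "A1": a1, "A2": a2,
        "A3": a1 / denom if denom != 0 else float("nan"),
        "A1_rv": a1 / rv if rv else float("nan"),
        "A2_rv": a2 / rv if rv else float("nan"),
    }
    return FeatureTable(feats, {"dVD_mm3": dvd, "dVC_mm3": dvc})


def diaphragm_excursion(tracked: TrackedMesh, partition: SurfacePartition,
                        lung: str = "right") -> FeatureTable:
    """Cranio-caudal diaphragm excursion features A4/A5.

    Per diaphragmatic triangle the CC displacement of its centroid relative
    to full inspiration, taken at the time of maximum magnitude (signed, so
    paradoxical caudal motion yields negative values); A4 is the
    area-weighted mean.  A5 (right lung only) splits the diaphragm at the
    mid-coronal plane of the reference bounding box (positions at full
    expiration) and reports posterior mean − anterior mean in mm.
    """
    dia = partition.diaphragmatic
    if len(dia) == 0:
        raise ValueError("empty diaphragmatic region")
    T = tracked.T
    z1 = tracked.centroids(1)[dia, 2]
    disp = np.stack([tracked.centroids(t)[dia, 2] - z1 for t in range(1, T + 1)])
    idx = np.argmax(np.abs(disp), axis=0)
    per_tri = disp[idx, np.arange(disp.shape[1])]
    areas = tracked.mesh.area_faces[dia]
    a4 = float(np.average(per_tri, weights=areas))

    feats = {"A4": a4}
    curves = {"excursion_mm": per_tri, "excursion_triangles": dia}
    if lung == "right":
        lo, hi = tracked.mesh.bounds
        y_mid = 0.5 * (lo[1] + hi[1])
        y_ref = tracked.mesh.triangles_center[dia, 1]  # full-expiration position
        post = y_ref < y_mid
        ant = ~post
        if post.any() and ant.any():
            post_mean = float(np.average(per_tri[post], weights=areas[post]))
            ant_mean = float(np.average(per_tri[ant], weights=areas[ant]))
            feats.update({"A5": post_mean - ant_mean,
                          "A4_posterior": post_mean, "A4_anterior": ant_mean})
        else:
            warnings.warn("degenerate anterior/posterior split", stacklevel=2)
            feats["A5"] = float("nan")
    else:
        feats["A5"] = float("nan")  # not applicable for the left lung
    return FeatureTable(feats, curves)


def _orientation_curve(tracked: TrackedMesh, dia: np.ndarray) -> np.ndarray:
    """Area-weighted mean sagittal-plane angle (deg) of the diaphragm
    normals vs the caudal (−z) axis, per frame; positive = posterior-low
    (backwards-tilted) dome."""
    faces = tracked.mesh.faces[dia]
    areas = tracked.mesh.area_faces[dia]
    out = np.empty(tracked.T)
    for t in range(1, tracked.T + 1):
        pos = tracked.positions[t - 1]
        tri = pos[faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        # faces winding is outward; for the diaphragm that points caudally
        ang = np.degrees(np.arctan2(n[:, 1], -n[:, 2]))
        out[t - 1] = float(np.average(ang, weights=areas))
    return out


def diaphragm_orientation(tracked: TrackedMesh, partition: SurfacePartition) -> FeatureTable:
    """Diaphragm dome orientation features A6/A7.

    A6 is the orientation at full inspiration.  The start/end of motion are
    the first frames reaching 10% and 90% of the total volume change; A7 is
    the signed extremum of orientation(t) − orientation(start) within that
    window."""
    dia = partition.diaphragmatic
    if len(dia) == 0:
        raise ValueError("empty diaphragmatic region")
    theta = _orientation_curve(tracked, dia)
    V = np.array([tracked.frame_volume(t) for t in range(1, tracked.T + 1)])
    cum = np.abs(V - V[0])
    total = cum[-1]
    feats = {"A6": float(theta[0])}
    if total <= 0:
        feats["A7"] = 0.0
        t_s = t_e = 0
    else:
        if np.any(np.diff(cum) < -1e-9 * max(total, 1.0)):
            warnings.warn("non-monotone volume curve; using first 10%/90% "
                          "crossings", stacklevel=2)
        t_s = int(np.argmax(cum >= 0.1 * total))
        t_e = int(np.argmax(cum >= 0.9 * total))
        window = theta[t_s:t_e + 1] - theta[t_s]
        feats["A7"] = float(window[np.argmax(np.abs(window))])
    return FeatureTable(feats, {"orientation_deg": theta,
                                "motion_window": np.array([t_s + 1, t_e + 1])})


def compute_features(tracked: TrackedMesh, partition: SurfacePartition,
                     lung: str = "right") -> FeatureTable:
    """All features B1–B6, A1–A7 and curves for one lung."""
    out = FeatureTable()
    for table in (basic_features(tracked, partition),
                  swept_volume_features(tracked, partition),
                  diaphragm_excursion(tracked, partition, lung=lung),
                  diaphragm_orientation(tracked, partition)):
        out.features.update(table.features)
        out.curves.update(table.curves)
    return out
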