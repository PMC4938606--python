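"""Watertight surface meshes from binary masks and their differential geometry.

The mesh is the central geometric object of the pipeline: a set of vertices V
(mm coordinates) and triangles F with consistent outward-oriented winding.
Everything downstream (partitioning, swept volumes, excursion maps) consumes
these meshes.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import trimesh
from scipy import ndimage

from .imagegrid import BinaryMask

# Empirical ratio between marching-cubes mean edge length and voxel pitch,
# used to pick the resampling pitch for a requested target edge length.
_MC_EDGE_PER_PITCH = 1.0


class SurfaceMesh(trimesh.Trimesh):
    """A watertight triangle mesh with outward normals.

    Subclasses :class:`trimesh.Trimesh`; construction validates
    watertightness and orientation (positive signed volume).
    """

    def __init__(self, vertices, faces, validate: bool = True, **kw):
        kw.setdefault("process", False)
        super().__init__(vertices=vertices, faces=faces, **kw)
        if validate:
            if not self.is_watertight:
                raise ValueError("mesh is not watertight")
            if self.volume < 0:
                self.invert()

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.faces)


def _largest_component(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    return max(parts, key=lambda m: len(m.faces))


def _resample_isotropic(data: np.ndarray, spacing, pitch: float) -> np.ndarray:
    """Linear resample onto an isotropic grid of the given pitch, keeping the
    physical position of index (0,0,0) fixed (output index j is at j*pitch)."""
    shape = [max(2, int(np.floor((n - 1) * s / pitch)) + 1)
             for n, s in zip(data.shape, spacing)]
    axes = [np.arange(m) * pitch / s for m, s in zip(shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(data, np.stack(coords), order=1, mode="nearest")


def extract_mesh(mask: BinaryMask, target_edge_mm: float = 4.0,
                 smooth_sigma_vox: float = 0.0) -> SurfaceMesh:
    """Extract a watertight boundary mesh from a binary mask (physical mm).

    The mask is linearly resampled to an isotropic pitch equal to
    ``target_edge_mm`` (marching-cubes mean edge length ~= the grid pitch,
    within ±30%) and meshed at the 0.5 level set of the resampled occupancy;
    the linear resampling already acts as an anti-staircase filter, and an
    optional extra Gaussian smoothing (``smooth_sigma_vox`` in resampled
    voxels) is off by default because it shrinks convex shapes.  The largest
    connected surface component is kept.
    """
    if mask.count == 0:
        raise ValueError("cannot mesh an empty mask")
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")

    pitch = target_edge_mm / _MC_EDGE_PER_PITCH

    data = mask.data.astype(float)
    resampled = _resample_isotropic(data, mask.spacing, pitch)
    if resampled.max() <= 0.5:
        # Target edge too coarse for this object; fall back to native spacing.
        pitch = float(min(mask.spacing))
        resampled = _resample_isotropic(data, mask.spacing, pitch)
    if smooth_sigma_vox > 0:
        resampled = ndimage.gaussian_filter(resampled, smooth_sigma_vox)
    padded = np.pad(resampled, 2, constant_values=0.0)
    if padded.max() <= 0.5:
        raise ValueError("foreground vanished during resampling/smoothing")

    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = (verts - 2.0) * pitch + np.asarray(mask.origin)

    raw = trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=False)
    raw = _largest_component(raw)
    raw.merge_vertices()
    if not raw.is_watertight:
        trimesh.repair.fill_holes(raw)
    if not raw.is_watertight:
        raise ValueError("mesh extraction produced a non-watertight surface")
    mesh = SurfaceMesh(raw.vertices, raw.faces)
    mean_edge = float(mesh.edges_unique_length.mean())
    if not (0.7 * target_edge_mm <= mean_edge <= 1.3 * target_edge_mm):
        warnings.warn(
            f"mean edge length {mean_edge:.2f} mm outside ±30% of target "
            f"{target_edge_mm:.2f} mm", stacklevel=2)
    return mesh


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Signed enclosed volume (mm³) via the divergence theorem.

    Positive for outward-oriented watertight meshes; computed directly from
    the triangle soup so reversed winding negates the result.
    """
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def _vertex_rings(mesh: trimesh.Trimesh, order: int = 2) -> list[np.ndarray]:
    """k-ring vertex neighborhoods (excluding the vertex itself)."""
    neighbors = mesh.vertex_neighbors
    rings = []
    for v in range(len(mesh.vertices)):
        seen = {v}
        frontier = {v}
        for _ in range(order):
            nxt = set()
            for u in frontier:
                nxt.update(neighbors[u])
            frontier = nxt - seen
            seen |= frontier
        seen.discard(v)
        rings.append(np.fromiter(seen, dtype=int))
    return rings


def principal_curvature_max(mesh: trimesh.Trimesh, ring_order: int = 2) -> np.ndarray:
    """Per-vertex maximal principal curvature κ_max (1/mm).

    Estimated by a quadric fit over the ``ring_order``-ring neighborhood in
    a local frame aligned with the outward vertex normal.  Sign convention:
    convex-outward regions (a sphere seen from outside) have κ_max > 0.
    """
    V = np.asarray(mesh.vertices, float)
    normals = np.asarray(mesh.vertex_normals, float)
    rings = _vertex_rings(mesh, order=ring_order)
    kmax = np.empty(len(V))
    for i, ring in enumerate(rings):
        if ring.size < 5:
            raise ValueError(f"vertex {i} has too small a neighborhood for a quadric fit")
        n = normals[i]
        # Build an orthonormal tangent frame (t1, t2, n).
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        t1 = np.cross(n, a)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        d = V[ring] - V[i]
        u, v, h = d @ t1, d @ t2, d @ n
        # h(u,v) ≈ ½(A u² + 2B uv + C v²) + D u + E v
        A = np.column_stack([0.5 * u * u, u * v, 0.5 * v * v, u, v])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        H = np.array([[coef[0], coef[1]], [coef[1], coef[2]]])
        # Surface bending away from the outward normal (h < 0) is convex.
        eigs = np.linalg.eigvalsh(-H)
        kmax[i] = eigs[-1]
    return kmax


class TriangleAdjacency:
    """Edge-sharing triangle adjacency of a watertight mesh.

    Graph nodes are triangle centroids p_i; edges join triangles sharing an
    undirected mesh edge.  Watertightness makes the graph 3-regular.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if not mesh.is_watertight:
            raise ValueError("triangle adjacency requires a watertight mesh")
        self.mesh = mesh
        pairs = np.asarray(mesh.face_adjacency)
        n = len(mesh.faces)
        counts = np.bincount(pairs.ravel(), minlength=n)
        if not np.all(counts == 3):
            raise ValueError("boundary or non-manifold edges found")
        nbr: list[list[int]] = [[] for _ in range(n)]
        for a, b in pairs:
            nbr[a].append(int(b))
            nbr[b].append(int(a))
        self.neighbors = [np.array(v, dtype=int) for v in nbr]
        self.pairs = pairs
        self.n = n

    def __len__(self) -> int:
        return self.n


def triangle_adjacency(mesh: trimesh.Trimesh) -> TriangleAdjacency:
    return TriangleAdjacency(mesh)


def erode_region(region: Iterable[int], adjacency: TriangleAdjacency,
                 strips: int = 2) -> np.ndarray:
    """Peel ``strips`` BFS layers of boundary triangles off a region.

    A boundary triangle is one adjacent to a non-region triangle; one strip
    is one BFS layer.  ``strips=0`` is the identity.  May return an empty
    set (with a warning) for small regions.
    """
    region = np.asarray(sorted(set(int(r) for r in region)), dtype=int)
    if region.size == 0:
        raise ValueError("region is empty")
    if strips < 0:
        raise ValueError("strips must be >= 0")
    member = np.zeros(adjacency.n, dtype=bool)
    member[region] = True
    current = member.copy()
    for _ in range(strips):
        boundary = [t for t in np.flatnonzero(current)
                    if any(not current[u] for u in adjacency.neighbors[t])]
        if not boundary:
            break
        current[boundary] = False
    out = np.flatnonzero(current)
    if out.size == 0 and strips > 0:
        warnings.warn("region fully eroded", stacklevel=2)
    return out
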