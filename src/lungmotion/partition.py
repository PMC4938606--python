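"""Anatomical partitioning of a lung surface mesh.

The surface is subdivided into three major regions — costal (adjacent to the
chest wall), medial (adjacent to the heart/mediastinum) and diaphragmatic —
in two stages:

1. a curvature-driven watershed oversegments the mesh into patches bounded
   by surface ridges, and patches close to the convex hull are merged into
   the costal surface (the costal surface is the only large convex region);
2. the residual (non-costal) surface is split into diaphragmatic vs medial
   by a random walker on the triangle-adjacency graph, seeded from
   anatomical rules (most-posterior patch → diaphragm; most-superior and
   occluded-from-below patches → medial) and iterated with additional
   random seeds until the partition stabilizes.

Costal triangles are further tagged anterior/posterior/superior/lateral for
visualization by the bounding-box face their normal ray exits through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .meshcore import SurfaceMesh, TriangleAdjacency, principal_curvature_max, triangle_adjacency

# triangle labels
COSTAL_ANTERIOR = 0
COSTAL_POSTERIOR = 1
COSTAL_SUPERIOR = 2
COSTAL_LATERAL = 3
MEDIAL = 4
DIAPHRAGMATIC = 5

LABEL_NAMES = {
    COSTAL_ANTERIOR: "costal_anterior",
    COSTAL_POSTERIOR: "costal_posterior",
    COSTAL_SUPERIOR: "costal_superior",
    COSTAL_LATERAL: "costal_lateral",
    MEDIAL: "medial",
    DIAPHRAGMATIC: "diaphragmatic",
}

COSTAL_LABELS = (COSTAL_ANTERIOR, COSTAL_POSTERIOR, COSTAL_SUPERIOR, COSTAL_LATERAL)


class AmbiguousSeedsError(RuntimeError):
    """Diaphragm and medial seed rules selected the same patch."""


@dataclass
class PartitionConfig:
    """Tunable parameters of the partitioning pipeline."""

    hull_dist_mm: float = 10.0      # costal rule: patch triangles closer than this
    hull_frac: float = 0.25         # ... for at least this fraction of the patch
    w1: float = 1.0                 # edge weight: centroid-distance coefficient
    w2: float = 1.0                 # edge weight: normal-deviation coefficient
    w3: float = 1.0                 # edge weight: normal-curvature coefficient
    normal_div_deg: float = 30.0    # patch label propagation: max normal divergence
    ridge_threshold: float = 0.15      # ... min mean inter-patch weight
    p_diaphragm: float = 0.8        # walker probability threshold, diaphragm
    p_medial: float = 0.6           # walker probability threshold, medial
    change_tol: float = 0.03        # stop when <3% of triangles change partition
    max_iter: int = 10
    seeds_per_triangles: int = 50   # 1 new random seed per this many triangles
    rng_seed: int = 0
    curvature_smooth_iters: int = 0  # neighbor-averaging passes on kappa_max
    ring_order: int = 2              # curvature quadric neighborhood
    occlusion_tol_mm: float = 4.0


@dataclass
class PatchMap:
    """Watershed patches: one patch id per triangle (each patch edge-connected)."""

    patch_id: np.ndarray                  # (M,) int
    mesh: SurfaceMesh

    def __post_init__(self) -> None:
        self.patch_id = np.asarray(self.patch_id, dtype=int)
        self.n_patches = int(self.patch_id.max()) + 1 if self.patch_id.size else 0
        areas = self.mesh.area_faces
        centroids = self.mesh.triangles_center
        normals = self.mesh.face_normals
        self.members = [np.flatnonzero(self.patch_id == p) for p in range(self.n_patches)]
        self.centroid = np.stack([
            np.average(centroids[m], axis=0, weights=areas[m]) for m in self.members])
        mn = np.stack([np.average(normals[m], axis=0, weights=areas[m]) for m in self.members])
        self.mean_normal = mn / np.linalg.norm(mn, axis=1, keepdims=True)
        self.area = np.array([areas[m].sum() for m in self.members])

    def restricted(self, triangles: np.ndarray) -> "PatchMap":
        """Patch map restricted to a triangle subset (patch ids renumbered,
        members outside the subset dropped, patches split if disconnected)."""
        mask = np.zeros(len(self.patch_id), bool)
        mask[triangles] = True
        sub = np.full(len(self.patch_id), -1)
        sub[mask] = self.patch_id[mask]
        return PatchMap(_relabel_components(self.mesh, sub), self.mesh)


def _relabel_components(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    """Renumber label regions into edge-connected components, 0..K-1 in
    deterministic (lowest-member-triangle) order; label<0 entries get -1...

    Entries with negative labels stay negative (excluded).
    """
    pairs = np.asarray(mesh.face_adjacency)
    same = (labels[pairs[:, 0]] == labels[pairs[:, 1]]) & (labels[pairs[:, 0]] >= 0)
    n = len(labels)
    graph = sparse.coo_matrix(
        (np.ones(same.sum()), (pairs[same, 0], pairs[same, 1])), shape=(n, n))
    ncomp, comp = sparse.csgraph.connected_components(graph, directed=False)
    comp = comp.copy()
    comp[labels < 0] = -1
    # renumber surviving components compactly and deterministically
    out = np.full(n, -1)
    next_id = 0
    for t in range(n):
        if comp[t] >= 0 and out[t] < 0:
            out[comp == comp[t]] = next_id
            next_id += 1
    return out


# ---------------------------------------------------------------------------
# Watershed
# ---------------------------------------------------------------------------

def mesh_watershed(mesh: SurfaceMesh, curvature: np.ndarray,
                   smooth_iters: int = 0) -> PatchMap:
    """Curvature watershed on the vertex graph, mapped to triangles.

    Basins grow from local-minimum plateaus of κ_max by ascending flood, so
    high-curvature ridge vertices end up on basin boundaries.  Triangles take
    the majority basin of their three vertices; three-way ties go to the
    basin with the lowest mean curvature.  ``smooth_iters`` neighbor-averaging
    passes may be applied to the curvature field first (estimator noise on
    voxel-derived meshes otherwise oversegments badly).
    """
    kappa = np.asarray(curvature, float).copy()
    if len(kappa) != len(mesh.vertices):
        raise ValueError("curvature must be per-vertex")
    neighbors = mesh.vertex_neighbors
    for _ in range(smooth_iters):
        kappa = np.array([(kappa[v] + kappa[nb].sum()) / (1 + len(nb))
                          for v, nb in enumerate(neighbors)])

    n = len(kappa)
    basin = np.full(n, -1)
    order = np.argsort(kappa, kind="stable")
    next_basin = 0
    for v in order:
        if basin[v] >= 0:
            continue
        assigned = [u for u in neighbors[v] if basin[u] >= 0]
        if assigned:
            best = min(assigned, key=lambda u: (kappa[u], basin[u]))
            basin[v] = basin[best]
        else:
            basin[v] = next_basin
            next_basin += 1
            # flood the equal-curvature plateau reachable from v
            stack = [v]
            while stack:
                u = stack.pop()
                for w in neighbors[u]:
                    if basin[w] < 0 and kappa[w] == kappa[v]:
                        basin[w] = basin[v]
                        stack.append(w)

    # triangle labels: majority vote of vertex basins
    fb = basin[mesh.faces]  # (M, 3)
    basin_mean = np.zeros(next_basin)
    for b in range(next_basin):
        basin_mean[b] = kappa[basin == b].mean()
    tri_label = np.empty(len(fb), dtype=int)
    for t, (a, b, c) in enumerate(fb):
        if a == b or a == c:
            tri_label[t] = a
        elif b == c:
            tri_label[t] = b
        else:
            tri_label[t] = min((a, b, c), key=lambda x: (basin_mean[x], x))
    return PatchMap(_relabel_components(mesh, tri_label), mesh)


# ---------------------------------------------------------------------------
# Costal surface
# ---------------------------------------------------------------------------

def hull_distances(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Distance of interior points to the mesh's convex-hull boundary
    (= min over hull facet planes of the inside plane distance)."""
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(np.asarray(mesh.vertices))
    except QhullError as exc:  # pragma: no cover - degenerate input
        raise ValueError(f"degenerate convex hull: {exc}") from exc
    eq = hull.equations  # (F, 4): n·x + b <= 0 inside
    d = -(points @ eq[:, :3].T + eq[:, 3])
    return np.maximum(d.min(axis=1), 0.0)


def extract_costal(mesh: SurfaceMesh, patches: PatchMap,
                   hull_dist_mm: float = 10.0, frac: float = 0.25) -> np.ndarray:
    """Triangles of all patches with >= ``frac`` of member triangles closer
    than ``hull_dist_mm`` (centroid to convex hull): the costal surface."""
    dist = hull_distances(mesh, mesh.triangles_center)
    keep = []
    for m in patches.members:
        if np.mean(dist[m] < hull_dist_mm) >= frac:
            keep.append(m)
    if not keep:
        return np.empty(0, dtype=int)
    return np.sort(np.concatenate(keep))


def subdivide_costal(mesh: SurfaceMesh, costal: np.ndarray) -> np.ndarray:
    """Label costal triangles by the lung-bounding-box face first hit by the
    outward normal ray from the triangle centroid (visualization labels).

    Medial hits map to lateral and inferior hits to posterior (the costal
    surface has no medial/inferior parts of its own).
    """
    costal = np.asarray(costal, dtype=int)
    lo, hi = mesh.bounds
    c = mesh.triangles_center[costal]
    n = mesh.face_normals[costal]
    with np.errstate(divide="ignore"):
        t_exit = np.where(n > 0, (hi - c) / n, np.where(n < 0, (lo - c) / n, np.inf))
    axis = np.argmin(t_exit, axis=1)
    assert np.all(np.isfinite(t_exit[np.arange(len(axis)), axis])), \
        "normal ray missed the bounding box"
    sign = np.take_along_axis(n, axis[:, None], axis=1)[:, 0] > 0
    out = np.empty(len(costal), dtype=int)
    out[(axis == 0)] = COSTAL_LATERAL                 # ±x: lateral (medial→lateral)
    out[(axis == 1) & sign] = COSTAL_ANTERIOR
    out[(axis == 1) & ~sign] = COSTAL_POSTERIOR
    out[(axis == 2) & sign] = COSTAL_SUPERIOR
    out[(axis == 2) & ~sign] = COSTAL_POSTERIOR       # inferior→posterior
    return out


# ---------------------------------------------------------------------------
# Edge weights and random walker
# ---------------------------------------------------------------------------

@dataclass
class EdgeWeights:
    """Weights w_ij ∈ (0,1] on the triangle-adjacency edges of a region.

    ``nodes`` are mesh triangle indices; ``pairs`` index into ``nodes``.
    """

    nodes: np.ndarray       # (N,) triangle ids in the region
    pairs: np.ndarray       # (E, 2) local node indices
    w: np.ndarray           # (E,) weights

    def node_index(self) -> dict[int, int]:
        return {int(t): i for i, t in enumerate(self.nodes)}


def edge_weights(mesh: SurfaceMesh, adjacency: TriangleAdjacency,
                 region: Sequence[int], w1: float = 1.0, w2: float = 1.0,
                 w3: float = 1.0) -> EdgeWeights:
    """Zhang-style geometric edge weights ``w_ij = exp(-d_ij²)`` with
    ``d_ij = w1·|p_i-p_j| + w2·|n_i-n_j| + w3·f(κ_ij)``.

    Centroid distances are normalized by their regional mean (scale-free);
    the normal curvature across an edge is the hinge estimate
    ``±|n_i-n_j| / (|p_i-p_j|/mean)``, positive for convex hinges, and
    ``f`` penalizes convex edges five-fold (region boundaries of interest —
    the dome and cardiac-notch rims — are convex ridges).
    """
    if min(w1, w2, w3) < 0:
        raise ValueError("weight coefficients must be nonnegative")
    region = np.asarray(sorted(set(int(t) for t in region)), dtype=int)
    in_region = np.zeros(adjacency.n, bool)
    in_region[region] = True
    pairs_all = adjacency.pairs
    keep = in_region[pairs_all[:, 0]] & in_region[pairs_all[:, 1]]
    pairs = pairs_all[keep]

    centroids = mesh.triangles_center
    normals = mesh.face_normals
    dp = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1)
    dn = np.linalg.norm(normals[pairs[:, 0]] - normals[pairs[:, 1]], axis=1)
    mean_len = dp.mean() if len(dp) else 1.0
    dp_n = dp / mean_len

    # hinge convexity: neighbor centroid below my tangent plane → convex
    rel = centroids[pairs[:, 1]] - centroids[pairs[:, 0]]
    convex = np.einsum("ij,ij->i", rel, normals[pairs[:, 0]]) < 0
    kappa = np.where(convex, 1.0, -1.0) * dn / np.maximum(dp_n, 1e-12)
    fk = np.where(kappa >= 0, 5.0 * kappa, np.abs(kappa))

    d = w1 * dp_n + w2 * dn + w3 * fk
    # floor keeps w in (0,1] numerically: exp(-d²) underflows to 0.0 across
    # degenerate hinges, which would disconnect the walker graph
    w = np.maximum(np.exp(-d ** 2), 1e-12)

    index = {int(t): i for i, t in enumerate(region)}
    local = np.vectorize(index.__getitem__)(pairs)
    return EdgeWeights(region, local, w)


def curvature_transfer(kappa: float) -> float:
    """The convex-emphasis transfer f(κ): 5κ for κ >= 0, |κ| otherwise."""
    return 5.0 * kappa if kappa >= 0 else abs(kappa)


@dataclass
class LabelProbabilities:
    nodes: np.ndarray          # triangle ids
    probabilities: np.ndarray  # (N, L)
    labels: tuple


def random_walker(weights: EdgeWeights, seeds: dict[int, int],
                  labels: tuple = (DIAPHRAGMATIC, MEDIAL)) -> LabelProbabilities:
    """Seeded random-walker probabilities on the weighted region graph.

    Solves the combinatorial Dirichlet problem: unseeded-node probabilities
    are harmonic for the weighted graph Laplacian with seed nodes clamped to
    their label indicators.  ``seeds`` maps *triangle id* → label.

    Unseeded nodes in components without any seed get uniform probabilities
    (with a warning).
    """
    n = len(weights.nodes)
    L = len(labels)
    node_of = weights.node_index()
    seed_idx = np.array([node_of[t] for t in seeds], dtype=int)
    seed_lab = np.array([labels.index(v) for v in seeds.values()], dtype=int)
    if len(seed_idx) == 0:
        raise ValueError("at least one seed required")

    prob = np.zeros((n, L))
    prob[seed_idx, seed_lab] = 1.0
    free = np.ones(n, bool)
    free[seed_idx] = False
    nf = int(free.sum())
    if nf == 0:
        return LabelProbabilities(weights.nodes, prob, labels)

    i, j = weights.pairs[:, 0], weights.pairs[:, 1]
    W = sparse.coo_matrix((np.concatenate([weights.w, weights.w]),
                           (np.concatenate([i, j]), np.concatenate([j, i]))),
                          shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    Lap = sparse.diags(deg) - W

    # unseeded components: give uniform probabilities
    comp_n, comp = sparse.csgraph.connected_components(W, directed=False)
    seeded_comps = set(comp[seed_idx].tolist())
    orphan = np.array([comp[v] not in seeded_comps for v in range(n)]) & free
    if orphan.any():
        warnings.warn(f"{int(orphan.sum())} nodes unreachable from any seed; "
                      "assigned uniform probabilities", stacklevel=2)
        prob[orphan] = 1.0 / L
        free = free & ~orphan
        nf = int(free.sum())

    if nf:
        fidx = np.flatnonzero(free)
        sidx = np.flatnonzero(~free)
        Luu = Lap[fidx][:, fidx].tocsc()
        Lus = Lap[fidx][:, sidx]
        B = -Lus @ prob[sidx]
        X = spsolve(Luu, sparse.csc_matrix(B))
        X = np.asarray(X.todense()) if sparse.issparse(X) else np.atleast_2d(X)
        if X.shape != (nf, L):
            X = X.reshape(nf, L)
        prob[fidx] = np.clip(X, 0.0, 1.0)
        # renormalize tiny numerical drift
        prob[fidx] /= prob[fidx].sum(axis=1, keepdims=True)
    return LabelProbabilities(weights.nodes, prob, labels)


# ---------------------------------------------------------------------------
# Seed selection
# ---------------------------------------------------------------------------

def _first_hit_lengths(mesh: SurfaceMesh, origin: np.ndarray,
                       targets: np.ndarray, chunk: int = 128) -> np.ndarray:
    """For rays origin→target (unit parameter at the target), the smallest
    positive hit parameter against all mesh triangles (vectorized
    Möller–Trumbore)."""
    tri = np.asarray(mesh.triangles)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    out = np.full(len(targets), np.inf)
    eps = 1e-12
    for a in range(0, len(targets), chunk):
        d = targets[a:a + chunk] - origin          # (R, 3)
        p = np.cross(d[:, None, :], e2[None, :, :])          # (R, M, 3)
        det = np.einsum("mj,rmj->rm", e1, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            s = origin - v0                                   # (M, 3)
            u = np.einsum("mj,rmj->rm", s, p) * inv
            q = np.cross(s, e1)                               # (M, 3)
            v = np.einsum("rj,mj->rm", d, q) * inv
            t = np.einsum("mj,mj->m", e2, q)[None, :] * inv
        ok = (np.abs(det) > eps) & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > eps)
        t = np.where(ok, t, np.inf)
        out[a:a + chunk] = t.min(axis=1)
    return out


def occluded_from_below(mesh: SurfaceMesh, triangles: np.ndarray,
                        tol_mm: float = 4.0) -> np.ndarray:
    """True for triangles whose centroid is hidden from a viewpoint centrally
    located below the lung (first ray hit is some closer surface)."""
    lo, hi = mesh.bounds
    centroid = mesh.vertices.mean(axis=0)
    view = np.array([centroid[0], centroid[1], lo[2] - 0.25 * (hi[2] - lo[2])])
    targets = mesh.triangles_center[np.asarray(triangles, int)]
    tmin = _first_hit_lengths(mesh, view, targets)
    ray_len = np.linalg.norm(targets - view, axis=1)
    return tmin < 1.0 - tol_mm / np.maximum(ray_len, 1e-9)


@dataclass
class SeedSelection:
    seeds: dict            # triangle id -> label (DIAPHRAGMATIC / MEDIAL)
    patch_label: np.ndarray  # per (restricted) patch: label or -1
    fully_labeled: bool


def select_seeds(mesh: SurfaceMesh, patches: PatchMap, weights: EdgeWeights,
                 normal_div_deg: float = 30.0,
                 ridge_threshold: float = 0.15,
                 occlusion_tol_mm: float = 2.0) -> SeedSelection:
    """Anatomical seed rules on the non-costal patches.

    (i) most-posterior patch → diaphragmatic; (ii) most-superior patch and
    (iii) patches partially occluded from a sub-lung viewpoint → medial;
    (iv) labels propagate to adjacent unlabeled patches whose mean normals
    diverge < ``normal_div_deg`` and whose mean inter-patch edge weight
    exceeds ``ridge_threshold`` (no separating ridge), until fixpoint;
    (v) one seed per labeled patch at its central triangle.
    """
    if patches.n_patches == 0:
        raise ValueError("empty non-costal region")
    label = np.full(patches.n_patches, -1)

    # extreme-position rules consider only patches of non-negligible size;
    # a 2-triangle sliver at the posterior rim is not "the posterior patch"
    sizes = np.array([len(m) for m in patches.members])
    big = np.flatnonzero((patches.area >= 0.002 * patches.area.sum()) & (sizes >= 5))
    if len(big) == 0:
        big = np.arange(patches.n_patches)
    posterior = int(big[np.argmin(patches.centroid[big, 1])])
    superior = int(big[np.argmax(patches.centroid[big, 2])])
    label[posterior] = DIAPHRAGMATIC
    if superior == posterior:
        raise AmbiguousSeedsError(
            "most-posterior and most-superior rules selected the same patch")
    label[superior] = MEDIAL

    region_tris = np.concatenate(patches.members)
    occ = occluded_from_below(mesh, region_tris, tol_mm=occlusion_tol_mm)
    occ_map = dict(zip(region_tris.tolist(), occ.tolist()))
    for p, m in enumerate(patches.members):
        if any(occ_map[int(t)] for t in m):
            if p == posterior:
                # the diaphragm rule wins; partial occlusion of the posterior
                # patch would make the seed rules contradict each other
                continue
            label[p] = MEDIAL

    # patch adjacency with mean inter-patch weights
    tri_patch = np.full(len(mesh.faces), -1)
    for p, m in enumerate(patches.members):
        tri_patch[m] = p
    gp = tri_patch[weights.nodes[weights.pairs]]  # (E, 2) patch per endpoint
    inter = gp[:, 0] != gp[:, 1]
    pair_w: dict[tuple, list] = {}
    for (pa, pb), wv in zip(gp[inter], weights.w[inter]):
        if pa < 0 or pb < 0:
            continue
        key = (min(pa, pb), max(pa, pb))
        pair_w.setdefault(key, []).append(wv)
    mean_w = {k: float(np.mean(v)) for k, v in pair_w.items()}

    cos_lim = np.cos(np.radians(normal_div_deg))
    changed = True
    while changed:
        changed = False
        for p in range(patches.n_patches):
            if label[p] >= 0:
                continue
            candidates = []
            for (pa, pb), wbar in mean_w.items():
                if p not in (pa, pb):
                    continue
                q = pb if pa == p else pa
                if label[q] < 0 or wbar <= ridge_threshold:
                    continue
                if patches.mean_normal[p] @ patches.mean_normal[q] <= cos_lim:
                    continue
                candidates.append((wbar, label[q]))
            if candidates:
                label[p] = max(candidates)[1]
                changed = True

    seeds = {}
    for p in range(patches.n_patches):
        if label[p] < 0:
            continue
        m = patches.members[p]
        d = np.linalg.norm(mesh.triangles_center[m] - patches.centroid[p], axis=1)
        seeds[int(m[np.argmin(d)])] = int(label[p])
    return SeedSelection(seeds, label, bool(np.all(label >= 0)))


# ---------------------------------------------------------------------------
# Iterative partition
# ---------------------------------------------------------------------------

@dataclass
class SurfacePartition:
    """Final per-triangle anatomical labels of a lung surface mesh."""

    labels: np.ndarray
    mesh: SurfaceMesh
    report: dict = field(default_factory=dict)

    @property
    def diaphragmatic(self) -> np.ndarray:
        return np.flatnonzero(self.labels == DIAPHRAGMATIC)

    @property
    def medial(self) -> np.ndarray:
        return np.flatnonzero(self.labels == MEDIAL)

    @property
    def costal(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.labels, COSTAL_LABELS))

    def label_names(self) -> np.ndarray:
        return np.array([LABEL_NAMES[int(l)] for l in self.labels])


def iterative_partition(mesh: SurfaceMesh, weights: EdgeWeights,
                        selection: SeedSelection, patches: PatchMap,
                        config: Optional[PartitionConfig] = None) -> tuple[np.ndarray, dict]:
    """Iterated random-walker split of the non-costal region into
    diaphragmatic vs medial triangles.

    Returns (labels over ``weights.nodes``, report).  If the seed-rule
    propagation already labeled every patch the walker is skipped and patch
    labels are used directly.
    """
    cfg = config or PartitionConfig()
    nodes = weights.nodes
    report: dict = {"walker_iterations": 0, "converged": True,
                    "fully_labeled": selection.fully_labeled}

    if selection.fully_labeled:
        tri_patch = np.full(len(mesh.faces), -1)
        for p, m in enumerate(patches.members):
            tri_patch[m] = p
        labels = np.array([selection.patch_label[tri_patch[t]] for t in nodes])
        return labels, report

    rng = np.random.default_rng(cfg.rng_seed)
    seeds = dict(selection.seeds)
    prev_d = prev_m = None
    converged = False
    prob = None
    for it in range(1, cfg.max_iter + 1):
        lp = random_walker(weights, seeds)
        prob = lp.probabilities
        part_d = prob[:, 0] > cfg.p_diaphragm
        part_m = prob[:, 1] > cfg.p_medial
        report["walker_iterations"] = it
        if prev_d is not None:
            changed = int((part_d != prev_d).sum() + (part_m != prev_m).sum())
            if changed / max(len(nodes), 1) < cfg.change_tol:
                converged = True
                break
        prev_d, prev_m = part_d, part_m
        for part, lab in ((part_d, DIAPHRAGMATIC), (part_m, MEDIAL)):
            cand = [i for i in np.flatnonzero(part) if int(nodes[i]) not in seeds]
            k = min(len(cand), max(0, int(part.sum()) // cfg.seeds_per_triangles))
            if k:
                pick = rng.choice(len(cand), size=k, replace=False)
                for i in pick:
                    seeds[int(nodes[cand[i]])] = lab
    else:
        converged = False
    report["converged"] = converged
    labels = np.where(prob[:, 0] > cfg.p_diaphragm, DIAPHRAGMATIC, MEDIAL)
    return labels, report


def partition_mesh(mesh: SurfaceMesh, config: Optional[PartitionConfig] = None,
                   curvature: Optional[np.ndarray] = None) -> SurfacePartition:
    """Full partitioning pipeline: watershed → costal extraction → seeded
    iterative random walker → per-triangle labels."""
    cfg = config or PartitionConfig()
    if curvature is None:
        curvature = principal_curvature_max(mesh, ring_order=cfg.ring_order)
    patches = mesh_watershed(mesh, curvature, smooth_iters=cfg.curvature_smooth_iters)
    costal = extract_costal(mesh, patches, cfg.hull_dist_mm, cfg.hull_frac)

    labels = np.full(len(mesh.faces), -1)
    if len(costal):
        labels[costal] = subdivide_costal(mesh, costal)

    rest = np.flatnonzero(labels < 0)
    if len(rest) == 0:
        raise ValueError("no non-costal surface left to partition")
    adjacency = triangle_adjacency(mesh)

    # absorb sliver components of the non-costal region into the costal
    # surface: isolated handfuls of triangles enclosed by costal patches
    # carry no anatomical meaning and would otherwise strand walker nodes
    comp = _relabel_components(mesh, np.where(labels < 0, 0, -1))
    min_comp = max(10, int(0.002 * len(mesh.faces)))
    for cid in range(comp.max() + 1):
        members = np.flatnonzero(comp == cid)
        if len(members) < min_comp:
            labels[members] = subdivide_costal(mesh, members)
    rest = np.flatnonzero(labels < 0)
    if len(rest) == 0:
        raise ValueError("no non-costal surface left to partition")
    weights = edge_weights(mesh, adjacency, rest, cfg.w1, cfg.w2, cfg.w3)
    sub_patches = patches.restricted(rest)
    selection = select_seeds(mesh, sub_patches, weights,
                             normal_div_deg=cfg.normal_div_deg,
                             ridge_threshold=cfg.ridge_threshold,
                             occlusion_tol_mm=cfg.occlusion_tol_mm)
    rest_labels, report = iterative_partition(mesh, weights, selection,
                                              sub_patches, cfg)
    labels[weights.nodes] = rest_labels

    report.update({
        "n_patches": patches.n_patches,
        "n_costal": int(len(costal)),
        "n_diaphragmatic": int((labels == DIAPHRAGMATIC).sum()),
        "n_medial": int((labels == MEDIAL).sum()),
        "label_counts": {LABEL_NAMES[k]: int((labels == k).sum()) for k in LABEL_NAMES},
    })
    return SurfacePartition(labels, mesh, report)
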