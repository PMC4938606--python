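"""Shared fixtures: geometric phantoms and the control-like dynamic lung."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from lungmotion import meshcore, phantom
from lungmotion.imagegrid import BinaryMask


def ball_mask(radius_mm: float = 25.0, spacing: float = 1.0) -> BinaryMask:
    n = int(2 * radius_mm / spacing) + 7
    c = (n // 2) * spacing
    ax = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return BinaryMask((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius_mm ** 2,
                      (spacing, spacing, spacing))


def two_balls_mask(radius=25.0, gap=30.0, spacing=1.0) -> BinaryMask:
    n = int((2 * radius + gap) / spacing) + 9
    cz = (n // 2) * spacing
    ax = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    c1 = cz - gap / 2
    c2 = cz + gap / 2
    d1 = (X - cz) ** 2 + (Y - c1) ** 2 + (Z - cz) ** 2 <= radius ** 2
    d2 = (X - cz) ** 2 + (Y - c2) ** 2 + (Z - cz) ** 2 <= radius ** 2
    return BinaryMask(d1 | d2, (spacing, spacing, spacing))


def analytic_cylinder(radius=20.0, height=80.0, n_phi=72, n_z=28) -> meshcore.SurfaceMesh:
    """Closed cylinder triangulated on a regular wall grid plus fan caps."""
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    zs = np.linspace(-height / 2, height / 2, n_z)
    ring = np.stack([radius * np.cos(phi), radius * np.sin(phi)], axis=1)
    verts = [np.column_stack([ring, np.full(n_phi, z)]) for z in zs]
    verts = np.concatenate(verts)
    faces = []
    for iz in range(n_z - 1):
        for ip in range(n_phi):
            a = iz * n_phi + ip
            b = iz * n_phi + (ip + 1) % n_phi
            c = a + n_phi
            d = b + n_phi
            faces += [[a, b, d], [a, d, c]]
    bot = len(verts)
    top = bot + 1
    verts = np.vstack([verts, [0, 0, -height / 2], [0, 0, height / 2]])
    for ip in range(n_phi):
        a, b = ip, (ip + 1) % n_phi
        faces.append([bot, b, a])
        a2 = (n_z - 1) * n_phi + ip
        b2 = (n_z - 1) * n_phi + (ip + 1) % n_phi
        faces.append([top, a2, b2])
    return meshcore.SurfaceMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=50.0)


@pytest.fixture(scope="session")
def control_phantom():
    """Control-like phantom: geometry, reference mesh, truth, curvature."""
    geom = phantom.PhantomGeometry(phantom.control_like(0))
    mask = geom.rasterize_frame(geom.T)
    mesh = meshcore.extract_mesh(mask, target_edge_mm=3.0)
    truth = phantom.PhantomTruth(geom)
    kappa = meshcore.principal_curvature_max(mesh)
    return {"geom": geom, "mask": mask, "mesh": mesh, "truth": truth, "kappa": kappa}


@pytest.fixture(scope="session")
def control_tracked(control_phantom):
    from lungmotion import kinematics

    geom = control_phantom["geom"]
    return kinematics.propagate_mesh(control_phantom["mesh"],
                                     geom.displacement_provider(), geom.T)


@pytest.fixture(scope="session")
def truth_partition(control_phantom):
    """Partition from analytic truth labels (boundary band folded to costal)."""
    from lungmotion import partition as pt

    lt = control_phantom["truth"].label_points(control_phantom["mesh"].triangles_center)
    labels = np.where(lt == phantom.DIAPHRAGMATIC, pt.DIAPHRAGMATIC,
                      np.where(lt == phantom.MEDIAL, pt.MEDIAL, pt.COSTAL_LATERAL))
    return pt.SurfacePartition(labels, control_phantom["mesh"])
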