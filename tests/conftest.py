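"""Shared geometric fixtures: analytic shapes with known curvature/volume."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from rvmap.mesh import SurfaceMesh, VentricularShell
from rvmap.simulate import TemplateSpec, make_template_context


def icosphere_mesh(radius: float, subdivisions: int = 4,
                   analytic_normals: bool = True) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(ico.vertices)
    normals = v / np.linalg.norm(v, axis=1, keepdims=True) if analytic_normals else None
    return SurfaceMesh(v, np.asarray(ico.faces), normals)


def ellipsoid_mesh(a: float, b: float, c: float, subdivisions: int = 4) -> SurfaceMesh:
    """Icosphere mapped onto an ellipsoid, with analytic outward normals."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    v = u * np.array([a, b, c])
    grad = v / np.array([a ** 2, b ** 2, c ** 2])
    normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    return SurfaceMesh(v, np.asarray(ico.faces), normals)


def capped_cylinder_mesh(radius: float = 10.0, height: float = 40.0,
                         nz: int = 24, nphi: int = 64) -> SurfaceMesh:
    zs = np.linspace(-height / 2, height / 2, nz)
    phi = np.arange(nphi) / nphi * 2 * np.pi
    verts = np.column_stack([radius * np.cos(np.tile(phi, nz)),
                             radius * np.sin(np.tile(phi, nz)),
                             np.repeat(zs, nphi)])
    faces = []
    for j in range(nz - 1):
        for i in range(nphi):
            a0 = j * nphi + i
            b0 = j * nphi + (i + 1) % nphi
            c0 = (j + 1) * nphi + i
            d0 = (j + 1) * nphi + (i + 1) % nphi
            faces += [[a0, b0, d0], [a0, d0, c0]]
    bc = len(verts)
    verts = np.vstack([verts, [0, 0, -height / 2], [0, 0, height / 2]])
    tc = bc + 1
    for i in range(nphi):
        faces.append([bc, (i + 1) % nphi, i])
        faces.append([tc, (nz - 1) * nphi + i, (nz - 1) * nphi + (i + 1) % nphi])
    return SurfaceMesh(verts, np.asarray(faces))


def sphere_shell(r_endo: float = 25.0, r_epi: float = 28.0,
                 subdivisions: int = 3) -> VentricularShell:
    endo = icosphere_mesh(r_endo, subdivisions)
    epi = icosphere_mesh(r_epi, subdivisions)
    return VentricularShell(endo, epi, np.zeros(endo.n_vertices, dtype=int))


@pytest.fixture(scope="session")
def template_ctx():
    """Desk-scale template (about 1000 vertices) shared across tests."""
    return make_template_context(TemplateSpec(n_vertices=1000))


@pytest.fixture(scope="session")
def sphere_shell_25_28():
    return sphere_shell()


@pytest.fixture(scope="session")
def ellipsoid_shells():
    """Nested ellipsoid shells 40/25/25 (endo) and 43/28/28 (epi), mm."""
    endo = ellipsoid_mesh(40.0, 25.0, 25.0)
    epi = ellipsoid_mesh(43.0, 28.0, 28.0)
    return VentricularShell(endo, epi, np.zeros(endo.n_vertices, dtype=int))
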