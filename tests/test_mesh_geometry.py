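"""Geometric phenotype operations against analytic and brute-force oracles."""

import numpy as np
import pytest
import trimesh

from rvmap.mesh import (CorrespondenceError, MeshStructureError, SurfaceMesh,
                        VentricularShell, VertexField, cavity_volume,
                        compute_curvature, compute_excursion,
                        compute_wall_thickness, inner_radius,
                        relative_wall_thickness, shape_deviation,
                        vertex_voronoi_areas)

from conftest import (capped_cylinder_mesh, ellipsoid_mesh, icosphere_mesh,
                      sphere_shell)


# ---------------------------------------------------------------------------
# wall thickness
# ---------------------------------------------------------------------------

class TestWallThickness:
    def test_concentric_spheres_give_radial_gap(self, sphere_shell_25_28):
        wt, fallback = compute_wall_thickness(sphere_shell_25_28)
        assert np.all(np.abs(wt.values - 3.0) / 3.0 < 0.02)
        assert not fallback.any()

    def test_identical_surfaces_give_zero(self):
        m = icosphere_mesh(25.0, 3)
        shell = VentricularShell(m, m, np.zeros(m.n_vertices, int))
        wt, _ = compute_wall_thickness(shell)
        assert np.all(wt.values == 0.0)

    def test_symmetric_under_endo_epi_swap(self, sphere_shell_25_28):
        s = sphere_shell_25_28
        swapped = VentricularShell(s.epi, s.endo, s.region_labels)
        wt_a, _ = compute_wall_thickness(s)
        wt_b, _ = compute_wall_thickness(swapped)
        np.testing.assert_allclose(wt_a.values, wt_b.values, rtol=1e-12)

    def test_rigid_motion_invariance(self, sphere_shell_25_28):
        s = sphere_shell_25_28
        rng = np.random.default_rng(7)
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = np.array([13.0, -4.0, 7.5])
        moved = VentricularShell(s.endo.transformed(q, t),
                                 s.epi.transformed(q, t), s.region_labels)
        wt_a, _ = compute_wall_thickness(s)
        wt_b, _ = compute_wall_thickness(moved)
        np.testing.assert_allclose(wt_b.values, wt_a.values, rtol=1e-9)

    def test_ellipsoid_shells_match_dense_ray_oracle(self, ellipsoid_shells):
        """Brute-force ray casting along exact normals onto a 10x denser
        epicardial mesh, written independently of the package's caster."""
        wt, _ = compute_wall_thickness(ellipsoid_shells)
        dense_epi = ellipsoid_mesh(43.0, 28.0, 28.0, subdivisions=6)
        origins = ellipsoid_shells.endo.vertices
        dirs = ellipsoid_shells.endo.normals
        oracle = _bruteforce_ray_distance(origins, dirs, dense_epi)
        ok = np.isfinite(oracle)
        assert ok.mean() > 0.99
        rel = np.abs(wt.values[ok] - oracle[ok]) / oracle[ok]
        assert np.percentile(rel, 99) < 0.03

    def test_open_mesh_rejected(self):
        m = icosphere_mesh(25.0, 2)
        open_faces = m.faces[:-4]
        open_endo = SurfaceMesh(m.vertices, open_faces)
        epi = icosphere_mesh(28.0, 2)
        shell = VentricularShell(open_endo, epi, np.zeros(m.n_vertices, int))
        with pytest.raises(MeshStructureError, match="boundary"):
            compute_wall_thickness(shell)


def _bruteforce_ray_distance(origins, dirs, target):
    """Minimal unoptimised Moller-Trumbore loop over every (ray, face) pair."""
    tri = target.vertices[target.faces]
    out = np.full(len(origins), np.inf)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    for i in range(len(origins)):
        o, d = origins[i], dirs[i]
        p = np.cross(d, e2)
        det = np.einsum("fj,fj->f", e1, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = o - v0
            u = np.einsum("fj,fj->f", s, p) / det
            qv = np.cross(s, e1)
            vpar = (qv @ d) / det
            t = np.einsum("fj,fj->f", e2, qv) / det
            hit = (np.abs(det) > 1e-12) & (u >= 0) & (vpar >= 0) & (u + vpar <= 1) & (t > 1e-9)
        if hit.any():
            out[i] = t[hit].min()
    return out


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

class TestCurvature:
    def test_sphere_principal_curvatures(self):
        m = icosphere_mesh(1.0, 4, analytic_normals=False)
        c = compute_curvature(m)
        assert np.all(np.abs(c.kappa1 - 1.0) < 0.02)
        assert np.all(np.abs(c.kappa2 - 1.0) < 0.02)

    def test_cylinder_curvatures_away_from_caps(self):
        m = capped_cylinder_mesh(radius=10.0, height=40.0)
        c = compute_curvature(m)
        side = np.abs(m.vertices[:, 2]) < 12.0
        assert np.all(np.abs(c.kappa1[side] - 0.1) / 0.1 < 0.03)
        assert np.all(np.abs(c.kappa2[side]) < 0.003)

    def test_planar_patch_is_flat(self):
        from scipy.spatial import Delaunay
        gx, gy = np.meshgrid(np.linspace(0, 10, 15), np.linspace(0, 10, 15))
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        tris = Delaunay(pts[:, :2]).simplices
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        c = compute_curvature(SurfaceMesh(pts, tris, normals))
        assert np.all(np.abs(c.kappa1) < 1e-6)
        assert np.all(np.abs(c.kappa2) < 1e-6)

    def test_convergence_with_refinement(self):
        errs = []
        for sub in range(2, 6):
            m = icosphere_mesh(1.0, sub, analytic_normals=False)
            c = compute_curvature(m)
            errs.append(np.abs(c.mean_curvature - 1.0).max())
        assert all(errs[i] > errs[i + 1] for i in range(len(errs) - 1))

    def test_kappa_ordering_holds_on_irregular_surface(self, template_ctx):
        c = compute_curvature(template_ctx.shell.endo)
        assert np.all(c.kappa1 + 1e-12 >= c.kappa2)
        assert np.all(np.isfinite(c.mean_curvature))


class TestInnerRadius:
    def test_sphere_radius_recovered(self):
        m = icosphere_mesh(25.0, 4)
        c = compute_curvature(m)
        r, clamped = inner_radius(c)
        assert np.all(np.abs(r.values - 25.0) / 25.0 < 0.02)
        assert not clamped.any()

    def test_flat_region_clamped_and_flagged(self):
        from scipy.spatial import Delaunay
        gx, gy = np.meshgrid(np.linspace(0, 10, 12), np.linspace(0, 10, 12))
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        tris = Delaunay(pts[:, :2]).simplices
        m = SurfaceMesh(pts, tris, np.tile([0.0, 0.0, 1.0], (len(pts), 1)))
        r, clamped = inner_radius(compute_curvature(m), floor=0.01)
        assert np.all(r.values == 100.0)
        assert clamped.all()

    def test_invalid_floor_rejected(self):
        m = icosphere_mesh(10.0, 2)
        with pytest.raises(ValueError):
            inner_radius(compute_curvature(m), floor=0.0)

    def test_ellipsoid_matches_analytic_mean_curvature(self):
        a, b, c = 40.0, 25.0, 25.0
        m = ellipsoid_mesh(a, b, c, subdivisions=4)
        curv = compute_curvature(m)
        r, _ = inner_radius(curv, floor=1e-6)
        h_true = _ellipsoid_mean_curvature(m.vertices, a, b, c)
        r_true = 1.0 / h_true
        rel = np.abs(r.values - r_true) / r_true
        assert np.percentile(rel, 99) < 0.03


def _ellipsoid_mean_curvature(pts, a, b, c):
    """H = div(n)/2 for the implicit ellipsoid, by central differences of the
    closed-form unit normal field n = grad F / |grad F|."""
    axes2 = np.array([a ** 2, b ** 2, c ** 2])

    def unit_normal(p):
        g = 2.0 * p / axes2
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    h = 1e-4
    div = np.zeros(len(pts))
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        div += (unit_normal(pts + dp)[:, k] - unit_normal(pts - dp)[:, k]) / (2 * h)
    return div / 2.0


# ---------------------------------------------------------------------------
# excursion / relative WT / shape deviation
# ---------------------------------------------------------------------------

class TestExcursion:
    def test_pure_translation_is_constant(self):
        m = icosphere_mesh(25.0, 3)
        moved = SurfaceMesh(m.vertices + np.array([3.0, 4.0, 0.0]), m.faces, m.normals)
        exc = compute_excursion(m, moved)
        np.testing.assert_allclose(exc.values, 5.0, rtol=1e-12)

    def test_identity_and_symmetry(self):
        m = icosphere_mesh(25.0, 3)
        assert np.all(compute_excursion(m, m).values == 0.0)
        other = SurfaceMesh(m.vertices * 1.07, m.faces, m.normals)
        np.testing.assert_array_equal(compute_excursion(m, other).values,
                                      compute_excursion(other, m).values)

    def test_contraction_about_centroid(self):
        m = icosphere_mesh(25.0, 3)
        centroid = m.vertices.mean(axis=0)
        shrunk = SurfaceMesh(centroid + 0.9 * (m.vertices - centroid),
                             m.faces, m.normals)
        exc = compute_excursion(m, shrunk)
        expected = 0.1 * np.linalg.norm(m.vertices - centroid, axis=1)
        np.testing.assert_allclose(exc.values, expected, rtol=1e-10)

    def test_topology_mismatch_rejected(self):
        with pytest.raises(CorrespondenceError):
            compute_excursion(icosphere_mesh(25.0, 3), icosphere_mesh(25.0, 2))


class TestRelativeWallThickness:
    def test_equal_volumes_identity(self):
        wt = VertexField(np.full(100, 3.0), units="mm")
        out = relative_wall_thickness(wt, 150.0, 150.0)
        np.testing.assert_array_equal(out.values, wt.values)

    def test_isotropic_inflation_invariance(self):
        wt = VertexField(np.linspace(2, 4, 50), units="mm")
        base = relative_wall_thickness(wt, 120.0, 100.0)
        inflated = VertexField(wt.values * 2.0, units="mm")
        out = relative_wall_thickness(inflated, 120.0 * 8.0, 100.0)
        np.testing.assert_allclose(out.values, base.values, rtol=1e-12)

    def test_cube_root_scaling_value(self):
        wt = VertexField(np.array([3.0]), units="mm")
        out = relative_wall_thickness(wt, 200.0, 100.0)
        assert out.values[0] == pytest.approx(3.0 * 0.5 ** (1 / 3), abs=5e-4)
        assert out.values[0] == pytest.approx(2.381, abs=5e-4)

    def test_nonpositive_volume_rejected(self):
        wt = VertexField(np.array([3.0]))
        with pytest.raises(ValueError):
            relative_wall_thickness(wt, 0.0, 100.0)


class TestShapeDeviation:
    def test_uniform_inflation_positive_one(self):
        template = icosphere_mesh(10.0, 3)
        subject = icosphere_mesh(11.0, 3)
        dev = shape_deviation(subject, template)
        np.testing.assert_allclose(dev.values, 1.0, atol=1e-9)

    def test_identity_zero(self):
        m = icosphere_mesh(10.0, 3)
        assert np.all(shape_deviation(m, m).values == 0.0)

    def test_tangential_motion_projects_out(self):
        template = icosphere_mesh(10.0, 3)
        n = template.normals
        rng = np.random.default_rng(3)
        t = rng.standard_normal((template.n_vertices, 3))
        t -= np.einsum("vc,vc->v", t, n)[:, None] * n       # tangent field
        t *= 0.01
        subject = SurfaceMesh(template.vertices + t, template.faces, n)
        dev = shape_deviation(subject, template)
        assert np.abs(dev.values).max() < 1e-12


# ---------------------------------------------------------------------------
# cavity volume
# ---------------------------------------------------------------------------

class TestCavityVolume:
    def test_icosphere_volume(self):
        m = icosphere_mesh(10.0, 4)
        assert cavity_volume(m) == pytest.approx(4.0 / 3.0 * np.pi, rel=0.01)

    def test_cube_volume_exact(self):
        box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
        m = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
        assert cavity_volume(m) == pytest.approx(1.0, rel=1e-12)

    def test_scaling_law(self):
        m = icosphere_mesh(10.0, 3)
        doubled = SurfaceMesh(m.vertices * 2.0, m.faces, m.normals)
        assert cavity_volume(doubled) == pytest.approx(8.0 * cavity_volume(m),
                                                       rel=1e-12)

    def test_open_mesh_reports_boundary_edges(self):
        m = icosphere_mesh(10.0, 2)
        open_mesh = SurfaceMesh(m.vertices, m.faces[:-2])
        with pytest.raises(MeshStructureError, match=r"\d+ boundary"):
            cavity_volume(open_mesh)

    def test_ellipsoid_against_voxelization_oracle(self):
        a, b, c = 40.0, 25.0, 25.0
        m = ellipsoid_mesh(a, b, c, subdivisions=4)
        step = 0.25
        xs = np.arange(-a, a, step) + step / 2
        ys = np.arange(-b, b, step) + step / 2
        zs = np.arange(-c, c, step) + step / 2
        inside = ((xs[:, None, None] / a) ** 2
                  + (ys[None, :, None] / b) ** 2
                  + (zs[None, None, :] / c) ** 2) <= 1.0
        voxel_ml = inside.sum() * step ** 3 / 1000.0
        assert cavity_volume(m) == pytest.approx(voxel_ml, rel=0.01)


def test_voronoi_areas_partition_total_surface(template_ctx):
    mesh = template_ctx.shell.endo
    areas = vertex_voronoi_areas(mesh)
    total = mesh.to_trimesh().area
    assert areas.sum() == pytest.approx(total, rel=1e-9)
    assert np.all(areas >= 0)
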