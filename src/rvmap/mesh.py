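"""Per-vertex geometric phenotypes on co-registered ventricular shell meshes.

All subjects share a template triangulation, so every per-vertex quantity is
directly comparable across subjects ("template correspondence"). Coordinates
are millimetres; volumes are reported in millilitres.

The phenotypes computed here are the regional descriptors used in 3D cardiac
atlas studies:

* wall thickness (WT): endo-to-epi distance measured perpendicular to the wall,
* relative WT: WT after isotropic rescaling to a reference cavity volume,
* principal curvatures of a surface (and the inner radius of curvature R=1/H
  feeding the Laplace wall-stress map),
* systolic excursion: displacement of corresponding points between phases,
* shape deviation: signed normal offset of a subject from the mean template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "REGION_NAMES",
    "REGION_CODES",
    "SurfaceMesh",
    "VentricularShell",
    "CurvatureField",
    "VertexField",
    "MeshStructureError",
    "CorrespondenceError",
    "compute_wall_thickness",
    "compute_curvature",
    "inner_radius",
    "compute_excursion",
    "relative_wall_thickness",
    "shape_deviation",
    "cavity_volume",
    "vertex_voronoi_areas",
]

# Region labelling convention shared by the whole package: integer codes stored
# as the per-vertex attribute "region" in mesh files. The RV free wall is
# every non-septal label.
REGION_NAMES = ("inlet", "outlet", "apical_trabecular", "septum")
REGION_CODES = {name: i for i, name in enumerate(REGION_NAMES)}
SEPTUM = REGION_CODES["septum"]


class MeshStructureError(ValueError):
    """Mesh violates a structural precondition (open, non-manifold...)."""


class CorrespondenceError(ValueError):
    """Meshes expected to share template topology do not."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangle surface mesh with per-vertex unit outward normals.

    ``normals`` may be supplied (e.g. analytic normals on synthetic shapes);
    otherwise angle-weighted normals are computed from the triangulation.
    "Outward" means away from the enclosed cavity.
    """

    vertices: np.ndarray          # (V, 3) float64, mm
    faces: np.ndarray             # (F, 3) int
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshStructureError("face indices exceed vertex count")
        if self.normals is None:
            self.normals = estimate_vertex_normals(self.vertices, self.faces)
        else:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise MeshStructureError("vertex normals must have unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, normals: np.ndarray | None = None) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), normals)

    def boundary_edge_count(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts == 1))

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly moved copy (rotation applied to normals as well)."""
        return SurfaceMesh(self.vertices @ rotation.T + translation,
                           self.faces, self.normals @ rotation.T)


@dataclass
class VentricularShell:
    """Endocardial + epicardial surfaces of one subject at one cardiac phase."""

    endo: SurfaceMesh
    epi: SurfaceMesh
    region_labels: np.ndarray     # (V,) int codes into REGION_NAMES
    phase: str = "ED"             # "ED" or "ES"
    subject_id: str = "template"

    def __post_init__(self) -> None:
        if self.endo.n_vertices != self.epi.n_vertices:
            raise CorrespondenceError(
                f"endo ({self.endo.n_vertices}) and epi ({self.epi.n_vertices}) "
                "must share the template vertex count")
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        if len(self.region_labels) != self.endo.n_vertices:
            raise CorrespondenceError("one region label per template vertex required")
        if self.region_labels.min() < 0 or self.region_labels.max() >= len(REGION_NAMES):
            raise ValueError("unknown region code")

    @property
    def free_wall_mask(self) -> np.ndarray:
        """Boolean mask of RV free-wall vertices (everything except septum)."""
        return self.region_labels != SEPTUM


@dataclass
class VertexField:
    """One scalar value per template vertex, with units and a validity mask."""

    values: np.ndarray
    units: str = ""
    name: str = ""
    mask: np.ndarray | None = None   # True where the value is NOT valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.values):
            raise ValueError("mask length must equal value length")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError(f"non-finite values outside mask in field {self.name!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (1/mm), kappa1 >= kappa2.

    Sign convention: positive where the surface is convex toward the cavity,
    i.e. the centre of curvature lies on the cavity side of the wall.
    """

    kappa1: np.ndarray
    kappa2: np.ndarray
    degenerate_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.kappa1 = np.asarray(self.kappa1, dtype=np.float64)
        self.kappa2 = np.asarray(self.kappa2, dtype=np.float64)
        if self.degenerate_mask is None:
            self.degenerate_mask = np.zeros(len(self.kappa1), dtype=bool)
        if np.any(self.kappa1 + 1e-12 < self.kappa2):
            raise ValueError("kappa1 must dominate kappa2")

    @property
    def mean_curvature(self) -> np.ndarray:
        return 0.5 * (self.kappa1 + self.kappa2)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _angle_weighted_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    m = trimesh.Trimesh(vertices, faces, process=False)
    n = trimesh.geometry.weighted_vertex_normals(
        len(vertices), m.faces, m.face_normals, m.face_angles, use_loop=False)
    n = np.asarray(n, dtype=np.float64)
    lens = np.linalg.norm(n, axis=1)
    lens[lens == 0] = 1.0
    return n / lens[:, None]


def estimate_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit vertex normals: angle-weighted average + one quadric refinement.

    The refinement fits a local paraboloid z = dx·x + dy·y + a·x² + b·xy + c·y²
    over each vertex's one-ring in the provisional tangent frame and replaces
    the normal by the fitted surface normal at the origin. This removes the
    O(h) bias that averaged normals carry at irregular vertices, which would
    otherwise dominate the curvature estimate. Vertices with fewer than five
    neighbours keep the angle-weighted normal.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    n0 = _angle_weighted_normals(vertices, faces)
    V = len(vertices)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.vstack([edges, edges[:, ::-1]]), axis=0)
    counts = np.bincount(edges[:, 0], minlength=V)
    maxval = int(counts.max()) if V else 0
    nbr = np.full((V, maxval), -1, dtype=np.int64)
    slot = np.zeros(V, dtype=np.int64)
    for a, b in edges:                      # edges are sorted by a
        nbr[a, slot[a]] = b
        slot[a] += 1
    valid = nbr >= 0
    nbr_safe = np.where(valid, nbr, 0)

    ni = n0
    u = _any_perpendicular(ni)
    w = np.cross(ni, u)
    d = vertices[nbr_safe] - vertices[:, None, :]       # (V, M, 3)
    x = np.einsum("vmc,vc->vm", d, u)
    y = np.einsum("vmc,vc->vm", d, w)
    z = np.einsum("vmc,vc->vm", d, ni)
    cols = np.stack([x, y, x * x, x * y, y * y], axis=2)   # (V, M, 5)
    cols = np.where(valid[:, :, None], cols, 0.0)
    zz = np.where(valid, z, 0.0)
    G = np.einsum("vmi,vmj->vij", cols, cols)
    r = np.einsum("vmi,vm->vi", cols, zz)
    G += 1e-14 * np.eye(5)
    ok = counts >= 5
    coef = np.zeros((V, 5))
    if np.any(ok):
        coef[ok] = np.linalg.solve(G[ok], r[ok, :, None])[..., 0]
    nn = ni - coef[:, 0:1] * u - coef[:, 1:2] * w
    nn /= np.linalg.norm(nn, axis=1, keepdims=True)
    nn[~ok] = n0[~ok]
    return nn


def vertex_voronoi_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Mixed Voronoi area per vertex (Meyer et al. mixed cells), mm^2.

    Obtuse triangles contribute half their area to the obtuse corner and a
    quarter to each other corner, keeping areas positive and summing exactly
    to the total surface area.
    """
    w = _corner_voronoi_weights(mesh.vertices, mesh.faces)
    out = np.zeros(mesh.n_vertices)
    for corner in range(3):
        np.add.at(out, mesh.faces[:, corner], w[:, corner])
    return out


def _raycast_first_hit(origins: np.ndarray, directions: np.ndarray,
                       target: SurfaceMesh, k: int = 48,
                       full_retry: bool = True) -> np.ndarray:
    """Distance along each ray to the first triangle hit of ``target``.

    Candidate triangles are pruned with a KD-tree on face centroids; with
    ``full_retry`` rays that miss all candidates are retried against the full
    face set (in chunks). Misses return +inf. Moller-Trumbore with small
    tolerances on the barycentric bounds so rays grazing shared edges still
    register.
    """
    tri = target.vertices[target.faces]             # (F, 3, 3)
    centroids = tri.mean(axis=1)
    kk = min(k, len(target.faces))
    _, cand = cKDTree(centroids).query(origins, k=kk)
    cand = np.atleast_2d(cand)
    t = _mt_min_t(origins, directions, tri, cand)
    if full_retry:
        missed = np.nonzero(~np.isfinite(t))[0]
        if missed.size:
            t[missed] = _raycast_dense(origins[missed], directions[missed], tri)
    return t


def _raycast_dense(origins: np.ndarray, directions: np.ndarray,
                   tri: np.ndarray, chunk: int = 64) -> np.ndarray:
    all_faces = np.arange(len(tri))
    out = np.empty(len(origins))
    for s in range(0, len(origins), chunk):
        e = min(s + chunk, len(origins))
        cand = np.broadcast_to(all_faces, (e - s, len(tri)))
        out[s:e] = _mt_min_t(origins[s:e], directions[s:e], tri, cand)
    return out


def _mt_min_t(origins: np.ndarray, directions: np.ndarray,
              tri: np.ndarray, cand: np.ndarray,
              eps: float = 1e-12, bary_tol: float = 1e-9,
              t_min: float = 1e-9) -> np.ndarray:
    v0 = tri[cand, 0]                      # (R, K, 3)
    e1 = tri[cand, 1] - v0
    e2 = tri[cand, 2] - v0
    d = directions[:, None, :]
    o = origins[:, None, :]
    p = np.cross(d, e2)
    det = np.einsum("rkc,rkc->rk", e1, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        s = o - v0
        u = np.einsum("rkc,rkc->rk", s, p) * inv
        q = np.cross(s, e1)
        vv = np.einsum("rkc,rkc->rk", np.broadcast_to(d, q.shape), q) * inv
        t = np.einsum("rkc,rkc->rk", e2, q) * inv
        hit = ((np.abs(det) > eps) & (u >= -bary_tol) & (vv >= -bary_tol)
               & (u + vv <= 1.0 + bary_tol) & (t > t_min))
    t = np.where(hit, t, np.inf)
    return t.min(axis=1)


def _nearest_surface_distance(points: np.ndarray, target: SurfaceMesh) -> np.ndarray:
    q = trimesh.proximity.ProximityQuery(target.to_trimesh())
    _, dist, _ = q.on_surface(points)
    return np.asarray(dist)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_wall_thickness(shell: VentricularShell,
                           require_manifold: bool = True) -> VertexField:
    """Per-vertex wall thickness (mm): endo-epi distance perpendicular to the wall.

    Implemented as the symmetric average of the normal-ray distance from the
    endocardium to the epicardium and from the epicardium to the endocardium,
    which approximates the distance measured perpendicular to a mid-wall
    surface without constructing that surface. Each directed distance is the
    smallest positive ray hit along +/- the vertex normal, so the measure is
    exactly symmetric under swapping the two surfaces. Rays that miss fall
    back to the closest-point distance and are flagged in the mask.
    """
    if require_manifold:
        for name, m in (("endo", shell.endo), ("epi", shell.epi)):
            nb = m.boundary_edge_count()
            if nb:
                raise MeshStructureError(f"{name} mesh is open ({nb} boundary edges)")
    d_endo, flag_a = _directed_wall_distance(shell.endo, shell.epi)
    d_epi, flag_b = _directed_wall_distance(shell.epi, shell.endo)
    wt = 0.5 * (d_endo + d_epi)
    return VertexField(wt, units="mm", name=f"wall_thickness_{shell.phase}",
                       mask=np.zeros(len(wt), bool)), (flag_a | flag_b)


def _directed_wall_distance(src: SurfaceMesh, dst: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    identical = (src.n_vertices == dst.n_vertices
                 and np.array_equal(src.vertices, dst.vertices))
    if identical:
        return np.zeros(src.n_vertices), np.zeros(src.n_vertices, bool)
    # the wall-crossing hit is always the near one, so candidate pruning can
    # skip the far side: only rays that miss in BOTH directions are retried
    # against the full face set, then against the closest point
    t_pos = _raycast_first_hit(src.vertices, src.normals, dst, full_retry=False)
    t_neg = _raycast_first_hit(src.vertices, -src.normals, dst, full_retry=False)
    d = np.minimum(t_pos, t_neg)
    missed = np.nonzero(~np.isfinite(d))[0]
    if missed.size:
        tri = dst.vertices[dst.faces]
        dp = _raycast_dense(src.vertices[missed], src.normals[missed], tri)
        dn = _raycast_dense(src.vertices[missed], -src.normals[missed], tri)
        d[missed] = np.minimum(dp, dn)
    fallback = ~np.isfinite(d)
    if np.any(fallback):
        d[fallback] = _nearest_surface_distance(src.vertices[fallback], dst)
    return d, fallback


def compute_curvature(mesh: SurfaceMesh) -> CurvatureField:
    """Per-vertex principal curvatures from a polyhedral surface sample.

    The second fundamental form is estimated on every triangle by finite
    differences of the vertex normals along the edges (a least-squares fit of
    the 2x2 shape operator in the face plane), then rotated into each incident
    vertex's tangent plane and averaged with mixed-Voronoi-area weights.
    Eigenvalues of the averaged tensor give kappa1 >= kappa2. Degenerate
    (zero-area) triangles are excluded; vertices supported only by degenerate
    triangles are flagged.
    """
    v, f, vn = mesh.vertices, mesh.faces, mesh.normals
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n0, n1, n2 = vn[f[:, 0]], vn[f[:, 1]], vn[f[:, 2]]
    e0 = p2 - p1          # edge opposite corner 0
    e1 = p0 - p2
    e2 = p1 - p0
    fn = np.cross(e2, -e1)                       # (p1-p0) x (p2-p0)
    area2 = np.linalg.norm(fn, axis=1)
    good = area2 > 1e-14
    fn_unit = np.zeros_like(fn)
    fn_unit[good] = fn[good] / area2[good, None]
    # orthonormal in-plane frame (u, w)
    u = np.zeros_like(e2)
    lens = np.linalg.norm(e2, axis=1)
    ok = lens > 0
    u[ok] = e2[ok] / lens[ok, None]
    w = np.cross(fn_unit, u)

    dn0 = n2 - n1
    dn1 = n0 - n2
    dn2 = n1 - n0

    def comp(vec):  # components of 3-vectors in the face frame
        return np.einsum("fc,fc->f", vec, u), np.einsum("fc,fc->f", vec, w)

    rows_e = [comp(e0), comp(e1), comp(e2)]
    rows_dn = [comp(dn0), comp(dn1), comp(dn2)]
    # least squares for symmetric II = [[a, b], [b, c]] from
    #   II @ (eu, ew)^T = (dnu, dnw)^T   for each of the three edges
    A = np.zeros((len(f), 3, 3))
    rhs = np.zeros((len(f), 3))
    for (eu, ew), (du, dw) in zip(rows_e, rows_dn):
        # equation 1: a*eu + b*ew = du
        A[:, 0, 0] += eu * eu
        A[:, 0, 1] += eu * ew
        A[:, 1, 0] += eu * ew
        A[:, 1, 1] += ew * ew + eu * eu
        A[:, 1, 2] += eu * ew
        A[:, 2, 1] += eu * ew
        A[:, 2, 2] += ew * ew
        rhs[:, 0] += eu * du
        rhs[:, 1] += ew * du + eu * dw
        rhs[:, 2] += ew * dw
    # regularize degenerate faces so solve succeeds; they carry zero weight
    A[~good] = np.eye(3)
    sol = np.linalg.solve(A, rhs[..., None])[..., 0]   # (F, 3): a, b, c per face
    a_f, b_f, c_f = sol[:, 0], sol[:, 1], sol[:, 2]

    # per-corner Voronoi weights
    areas_w = _corner_voronoi_weights(v, f)
    areas_w[~good] = 0.0

    # vertex tangent frames
    up = _any_perpendicular(vn)
    wp = np.cross(vn, up)

    acc = np.zeros((mesh.n_vertices, 3))
    wsum = np.zeros(mesh.n_vertices)
    for corner in range(3):
        vid = f[:, corner]
        nv = vn[vid]
        # rotate the face frame into the vertex tangent plane (about fn x nv)
        ru, rw = _rotate_pair_into(u, w, fn_unit, nv)
        # components of the vertex frame in the rotated face frame
        u1 = np.einsum("fc,fc->f", up[vid], ru)
        u2 = np.einsum("fc,fc->f", up[vid], rw)
        v1 = np.einsum("fc,fc->f", wp[vid], ru)
        v2 = np.einsum("fc,fc->f", wp[vid], rw)
        av = a_f * u1 * u1 + 2 * b_f * u1 * u2 + c_f * u2 * u2
        bv = a_f * u1 * v1 + b_f * (u1 * v2 + u2 * v1) + c_f * u2 * v2
        cv = a_f * v1 * v1 + 2 * b_f * v1 * v2 + c_f * v2 * v2
        wgt = areas_w[:, corner]
        np.add.at(acc, vid, np.column_stack([av, bv, cv]) * wgt[:, None])
        np.add.at(wsum, vid, wgt)

    flagged = wsum <= 1e-14
    wsum_safe = np.where(flagged, 1.0, wsum)
    a, b, c = (acc[:, i] / wsum_safe for i in range(3))
    half_tr = 0.5 * (a + c)
    disc = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b * b, 0.0))
    kappa1 = half_tr + disc
    kappa2 = half_tr - disc
    kappa1[flagged] = 0.0
    kappa2[flagged] = 0.0
    return CurvatureField(kappa1, kappa2, degenerate_mask=flagged)


def _corner_voronoi_weights(v: np.ndarray, f: np.ndarray) -> np.ndarray:
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    l0 = np.sum((p2 - p1) ** 2, axis=1)
    l1 = np.sum((p0 - p2) ** 2, axis=1)
    l2 = np.sum((p1 - p0) ** 2, axis=1)
    area2 = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    area = 0.5 * area2
    with np.errstate(divide="ignore", invalid="ignore"):
        cot0 = (l1 + l2 - l0) / (2.0 * area2)
        cot1 = (l2 + l0 - l1) / (2.0 * area2)
        cot2 = (l0 + l1 - l2) / (2.0 * area2)
    w = np.zeros((len(f), 3))
    w[:, 0] = (l1 * cot1 + l2 * cot2) / 8.0
    w[:, 1] = (l2 * cot2 + l0 * cot0) / 8.0
    w[:, 2] = (l0 * cot0 + l1 * cot1) / 8.0
    obt = np.stack([cot0 < 0, cot1 < 0, cot2 < 0], axis=1)
    any_obt = obt.any(axis=1)
    for i in range(3):
        sel = any_obt & obt[:, i]
        w[sel] = area[sel, None] / 4.0
        w[sel, i] = area[sel] / 2.0
    w[area2 <= 1e-14] = 0.0
    return w


def _any_perpendicular(n: np.ndarray) -> np.ndarray:
    ref = np.zeros_like(n)
    use_x = np.abs(n[:, 0]) < 0.9
    ref[use_x, 0] = 1.0
    ref[~use_x, 1] = 1.0
    u = np.cross(n, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u


def _rotate_pair_into(u: np.ndarray, w: np.ndarray,
                      n_from: np.ndarray, n_to: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate frame vectors u, w by the rotation taking n_from onto n_to."""
    axis = np.cross(n_from, n_to)
    s = np.linalg.norm(axis, axis=1)
    c = np.einsum("fc,fc->f", n_from, n_to)
    out_u = u.copy()
    out_w = w.copy()
    rot = s > 1e-12
    if np.any(rot):
        k = axis[rot] / s[rot, None]
        for src, dst in ((u, out_u), (w, out_w)):
            x = src[rot]
            dst[rot] = (x * c[rot, None]
                        + np.cross(k, x) * s[rot, None]
                        + k * np.einsum("fc,fc->f", k, x)[:, None] * (1 - c[rot, None]))
    # antiparallel normals (c ~ -1, s ~ 0): flip through any perpendicular axis
    flip = (~rot) & (c < 0)
    if np.any(flip):
        k = _any_perpendicular(n_from[flip])
        for src, dst in ((u, out_u), (w, out_w)):
            x = src[flip]
            dst[flip] = 2 * k * np.einsum("fc,fc->f", k, x)[:, None] - x
    return out_u, out_w


def inner_radius(curv: CurvatureField, floor: float = 0.01) -> VertexField:
    """Inner radius of curvature R = 1/max(H, floor) in mm.

    ``floor`` (1/mm) caps R on flat or saddle-shaped patches where mean
    curvature H would otherwise make the Laplace stress blow up; clamped
    vertices are flagged in the field mask (values retained).
    """
    if floor <= 0:
        raise ValueError("curvature floor must be positive")
    H = curv.mean_curvature
    clamped = (H <= floor) | curv.degenerate_mask
    R = 1.0 / np.maximum(H, floor)
    fld = VertexField(R, units="mm", name="inner_radius")
    fld.mask = np.zeros(len(R), bool)       # values valid everywhere
    return fld, clamped


def compute_excursion(mesh_ed: SurfaceMesh, mesh_es: SurfaceMesh) -> VertexField:
    """Per-vertex displacement magnitude between end-diastole and end-systole."""
    if mesh_ed.n_vertices != mesh_es.n_vertices:
        raise CorrespondenceError("phases must share the template vertex count")
    d = np.linalg.norm(mesh_es.vertices - mesh_ed.vertices, axis=1)
    return VertexField(d, units="mm", name="excursion")


def relative_wall_thickness(wt: VertexField, cavity_volume_subject: float,
                            cavity_volume_template: float) -> VertexField:
    """WT rescaled to the template cavity volume: WT * (V_t / V_s)^(1/3).

    Separates hypertrophy from dilatation: an isotropically inflated ventricle
    (WT and volume scaled together) maps back onto the template values.
    """
    if cavity_volume_subject <= 0 or cavity_volume_template <= 0:
        raise ValueError("cavity volumes must be positive")
    scale = (cavity_volume_template / cavity_volume_subject) ** (1.0 / 3.0)
    return VertexField(wt.values * scale, units="mm",
                       name="relative_" + (wt.name or "wall_thickness"),
                       mask=wt.mask.copy())


def shape_deviation(subject_endo: SurfaceMesh, template_endo: SurfaceMesh) -> VertexField:
    """Signed normal offset of a subject surface from the mean template (mm).

    Positive values are outward displacement (dilatation); tangential sliding
    along the surface projects to ~zero.
    """
    if subject_endo.n_vertices != template_endo.n_vertices:
        raise CorrespondenceError("subject and template must share topology")
    disp = subject_endo.vertices - template_endo.vertices
    signed = np.einsum("vc,vc->v", disp, template_endo.normals)
    return VertexField(signed, units="mm", name="shape_deviation")


def cavity_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mL) by the divergence theorem; requires a closed mesh."""
    nb = mesh.boundary_edge_count()
    if nb:
        raise MeshStructureError(f"open mesh: {nb} boundary edges")
    v, f = mesh.vertices, mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    vol_mm3 = np.einsum("fc,fc->f", p0, np.cross(p1, p2)).sum() / 6.0
    return float(vol_mm3) / 1000.0
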