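"""Mesh and landmark geometry: anatomical frames, joint-surface fits and the
three-step bone morphing scheme (affine, tri-harmonic RBF, reverse rigid).

All lengths are SI metres internally.  Clinical STL files are conventionally
millimetres, so :func:`load_stl` converts on read unless told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


class DegenerateGeometryError(ValueError):
    """Raised when a fit or frame construction receives a singular configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated surface with vertices in metres."""

    vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (M, 3) int
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError(f"mesh {self.label!r}: non-finite vertex coordinates")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError(f"mesh {self.label!r}: face index out of range")

    @property
    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        areas = 0.5 * area2
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(area2[:, None] > 0, cross / np.where(area2 == 0, 1, area2)[:, None], 0.0)
        return normals, areas

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def drop_degenerate_faces(self, tol: float = 1e-16) -> "SurfaceMesh":
        _, areas = self.face_normals_areas
        return SurfaceMesh(self.vertices, self.faces[areas > tol], self.label)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) > 1e-9:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform.fast(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform.fast(self.rotation @ other.rotation,
                                   self.rotation @ other.translation + self.translation)

    @classmethod
    def fast(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        """Construct without the orthonormality checks (trusted hot paths:
        products/inverses of already-validated transforms)."""
        obj = cls.__new__(cls)
        obj.rotation = rotation
        obj.translation = translation
        return obj

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class AffineTransform:
    """General affine transform x -> A x + t."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) <= 1e-12:
            raise ValueError("affine linear part is numerically singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.linear.T + self.translation

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(3), np.zeros(3))


@dataclass
class RBFMorph:
    """Tri-harmonic (phi(r) = r^3) RBF interpolant with a full linear tail.

    Evaluation: f(x) = sum_i w_i * |x - c_i|^3 + A x + t, with the usual
    side conditions sum w_i = 0, sum w_i c_i^T = 0 so the polynomial tail
    absorbs all affine content.
    """

    control_points: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N, 3)
    affine_tail: AffineTransform = field(default_factory=AffineTransform.identity)

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.control_points.shape:
            raise ValueError("weights and control points must align one-to-one")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(points[:, None, :] - self.control_points[None, :, :], axis=2)
        return d**3 @ self.weights + self.affine_tail.apply(points)


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame; columns of ``axes`` are x, y, z."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.linalg.norm(self.axes.T @ self.axes - np.eye(3)) > 1e-9:
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame is left-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.axes

    def to_global(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.axes.T + self.origin


# ---------------------------------------------------------------------------
# STL / landmark I/O
# ---------------------------------------------------------------------------


def load_stl(path, label: str = "", scale: float = 1e-3) -> SurfaceMesh:
    """Read an STL file.  ``scale`` converts file units to metres (clinical
    STLs are mm, hence the 1e-3 default; pass 1.0 for files already in m)."""
    tm = trimesh.load_mesh(path, process=False)
    mesh = SurfaceMesh(np.asarray(tm.vertices) * scale, np.asarray(tm.faces), label or str(path))
    return mesh.drop_degenerate_faces()


def save_stl(mesh: SurfaceMesh, path, scale: float = 1e3) -> None:
    """Write an STL file; ``scale`` converts metres to file units (default mm)."""
    tm = trimesh.Trimesh(mesh.vertices * scale, mesh.faces, process=False)
    tm.export(path)


# ---------------------------------------------------------------------------
# fitting operations
# ---------------------------------------------------------------------------


def fit_affine(source_points: np.ndarray, target_points: np.ndarray) -> AffineTransform:
    """Least-squares affine map A s + t minimising sum ||A s_i + t - t_i||^2.

    Requires >= 4 non-coplanar source points.
    """
    S = np.asarray(source_points, dtype=float)
    T = np.asarray(target_points, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3:
        raise ValueError("source and target must both be (N, 3)")
    if len(S) < 4:
        raise DegenerateGeometryError("affine fit needs at least 4 points")
    centered = S - S.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-12 * max(1.0, sv[0]):
        raise DegenerateGeometryError("source points are coplanar; affine fit is singular")
    X = np.hstack([S, np.ones((len(S), 1))])
    sol, *_ = np.linalg.lstsq(X, T, rcond=None)
    return AffineTransform(sol[:3].T, sol[3])


def fit_rigid(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Kabsch orthogonal-Procrustes rigid fit (rotation + translation)."""
    S = np.asarray(source_points, dtype=float)
    T = np.asarray(target_points, dtype=float)
    cs, ct = S.mean(axis=0), T.mean(axis=0)
    H = (S - cs).T @ (T - ct)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ct - R @ cs)


def fit_triharmonic_rbf(source_points: np.ndarray, target_points: np.ndarray) -> RBFMorph:
    """Exact tri-harmonic RBF interpolant from source to target points.

    Solves the symmetric polyharmonic system with a full linear polynomial
    tail and orthogonality side conditions on the weights.
    """
    S = np.asarray(source_points, dtype=float)
    T = np.asarray(target_points, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3:
        raise ValueError("source and target must both be (N, 3)")
    n = len(S)
    if n < 4:
        raise DegenerateGeometryError("RBF fit needs at least 4 control points")
    d = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=2)
    dup = np.argwhere((d + np.eye(n)) <= 1e-9)
    if dup.size:
        i, j = dup[0]
        raise ValueError(f"duplicate source control points at indices {i} and {j}")
    K = d**3
    P = np.hstack([S, np.ones((n, 1))])  # (n, 4)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = T
    sol = np.linalg.solve(A, rhs)
    weights = sol[:n]
    tail = sol[n:]  # rows: x, y, z coeffs then constant
    return RBFMorph(S, weights, AffineTransform(tail[:3].T, tail[3]))


def morph_bone(source_mesh: SurfaceMesh, target_mesh: SurfaceMesh) -> tuple[SurfaceMesh, dict]:
    """Three-step bone morphing with one-to-one vertex correspondence.

    1. affine registration of source vertices onto target vertices,
    2. tri-harmonic RBF interpolation fixing the residual shape difference,
    3. reverse rigid-body transform (Procrustes between the morphed points
       and the original, pre-affine source) carrying the result back into
       the source frame.

    Returns the morphed mesh and a transform record (affine, RBF, rigid).
    """
    if len(source_mesh.vertices) != len(target_mesh.vertices):
        raise ValueError(
            "vertex correspondence error: source has "
            f"{len(source_mesh.vertices)} vertices, target {len(target_mesh.vertices)}"
        )
    affine = fit_affine(source_mesh.vertices, target_mesh.vertices)
    staged = affine.apply(source_mesh.vertices)
    rbf = fit_triharmonic_rbf(staged, target_mesh.vertices)
    morphed = rbf.apply(staged)
    reverse = fit_rigid(morphed, source_mesh.vertices)
    out = reverse.apply(morphed)
    record = {"affine": affine, "rbf": rbf, "reverse_rigid": reverse}
    return SurfaceMesh(out, source_mesh.faces.copy(), source_mesh.label + ":morphed"), record


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Returns (center, radius, rms_residual).  Used for hip and talocrural /
    subtalar joint centres from articular-surface points.
    """
    P = np.asarray(points, dtype=float)
    if len(P) < 4:
        raise DegenerateGeometryError("sphere fit needs at least 4 points")
    sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-10 * max(1.0, sv[0]):
        raise DegenerateGeometryError("points are coplanar; sphere fit is degenerate")
    # |x|^2 = 2 c.x + (r^2 - |c|^2)
    A = np.hstack([2 * P, np.ones((len(P), 1))])
    b = (P**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    radius = float(np.sqrt(max(r2, 0.0)))
    rms = float(np.sqrt(np.mean((np.linalg.norm(P - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def fit_circle_in_plane(points: np.ndarray, plane_normal: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle of points projected onto the plane with the given
    normal; the centre is lifted back to the mean out-of-plane offset.

    Condylar circle fits in the sagittal plane use this; the hinge axis runs
    through the two condylar circle centres.
    """
    P = np.asarray(points, dtype=float)
    u, v, n = _plane_basis(plane_normal)
    if len(P) < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    xy = np.column_stack([P @ u, P @ v])
    span = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if span[-1] < 1e-12 * max(1.0, span[0]):
        raise DegenerateGeometryError("projected points are collinear; circle fit is degenerate")
    A = np.hstack([2 * xy, np.ones((len(P), 1))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cxy = sol[:2]
    radius = float(np.sqrt(max(sol[2] + cxy @ cxy, 0.0)))
    offset = float(np.mean(P @ n))
    center = cxy[0] * u + cxy[1] * v + offset * n
    return center, radius


def hinge_axis_from_circles(medial_points: np.ndarray, lateral_points: np.ndarray,
                            plane_normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hinge origin (midpoint of the two condylar circle centres) and unit axis."""
    cm, _ = fit_circle_in_plane(medial_points, plane_normal)
    cl, _ = fit_circle_in_plane(lateral_points, plane_normal)
    axis = cm - cl
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise DegenerateGeometryError("condylar circle centres coincide; hinge axis undefined")
    return 0.5 * (cm + cl), axis / nrm


def build_fea_frame(medial_epicondyle: np.ndarray, lateral_epicondyle: np.ndarray,
                    hip_center: np.ndarray) -> AnatomicalFrame:
    """FEA coordinate system of a right-side bone.

    x from the lateral to the medial epicondyle, y orthogonalised towards the
    hip joint centre, z = x cross y; origin midway between the epicondyles.
    """
    med = np.asarray(medial_epicondyle, dtype=float)
    lat = np.asarray(lateral_epicondyle, dtype=float)
    hip = np.asarray(hip_center, dtype=float)
    x = med - lat
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise DegenerateGeometryError("epicondyles coincide")
    x = x / nx
    origin = 0.5 * (med + lat)
    y = hip - origin
    y = y - (y @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise DegenerateGeometryError("hip centre lies on the epicondylar line")
    y = y / ny
    z = np.cross(x, y)
    return AnatomicalFrame(origin, np.column_stack([x, y, z]))


# ---------------------------------------------------------------------------
# proximity helper (no rtree dependency)
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest point on a triangle soup for each query point.

    ``triangles`` is (M, 3, 3).  Returns (closest, distance, triangle_index).
    Vectorised brute force: fine for the desk-scale contact meshes used here.
    """
    P = np.atleast_2d(points)[:, None, :]  # (n, 1, 3)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac = b - a, c - a
    ap = P - a  # (n, m, 3)
    d1 = np.einsum("mk,nmk->nm", ab, ap)
    d2 = np.einsum("mk,nmk->nm", ac, ap)
    bp = P - b
    d3 = np.einsum("mk,nmk->nm", ab, bp)
    d4 = np.einsum("mk,nmk->nm", ac, bp)
    cp = P - c
    d5 = np.einsum("mk,nmk->nm", ab, cp)
    d6 = np.einsum("mk,nmk->nm", ac, cp)

    # barycentric regions (Ericson, Real-Time Collision Detection)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    cand = a + v[..., None] * ab + w[..., None] * ac  # interior projection

    # edge / vertex regions
    t_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0), 0, 1)
    on_ab = a + t_ab[..., None] * ab
    t_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0), 0, 1)
    on_ac = a + t_ac[..., None] * ac
    num_bc = d4 - d3
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(np.where(den_bc != 0, num_bc / np.where(den_bc == 0, 1, den_bc), 0.0), 0, 1)
    on_bc = b + t_bc[..., None] * (c - b)

    cand = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None], on_ab, cand)
    cand = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None], on_ac, cand)
    cand = np.where(((va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0))[..., None], on_bc, cand)
    cand = np.where(((d1 <= 0) & (d2 <= 0))[..., None], np.broadcast_to(a, cand.shape), cand)
    cand = np.where(((d3 >= 0) & (d4 <= d3))[..., None], np.broadcast_to(b, cand.shape), cand)
    cand = np.where(((d6 >= 0) & (d5 <= d6))[..., None], np.broadcast_to(c, cand.shape), cand)

    dist = np.linalg.norm(cand - P, axis=2)  # (n, m)
    idx = np.argmin(dist, axis=1)
    rows = np.arange(len(idx))
    return cand[rows, idx], dist[rows, idx], idx
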