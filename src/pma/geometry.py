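"""Geometric primitives for probability-cloud connectomics.

All coordinates are micrometres in a right-handed Cartesian frame.  The
module provides the low-level pieces the connection algorithm composes:
oriented ellipsoids and cones (the axonal / dendritic probability clouds),
orthonormal orientation frames anchored to anatomical landmarks,
volume-filling point clouds, convex hulls in half-space form, and
axis-aligned bounding boxes with closed-interval overlap tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import trimesh as _trimesh
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateFrameError, GeometryError

logger = logging.getLogger(__name__)

#: absolute tolerance for inclusive containment tests (µm scale)
CONTAIN_TOL = 1e-9

#: voxel side (µm) such that one cloud point represents one voxel volume
DEFAULT_VOXEL_SIDE = 20.0

#: volume (µm³) represented by a single dendritic cloud point
POINT_VOLUME = DEFAULT_VOXEL_SIDE ** 3


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise GeometryError(f"non-finite coordinates: {p}")
    return p


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) point array, got shape {pts.shape}")
    return pts


# ---------------------------------------------------------------------------
# orientation frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationFrame:
    """Right-handed orthonormal triad (u1, u2, u3).

    For pyramidal cells u1 is the transversal direction (toward the
    subiculum), u2 the longitudinal direction and u3 the vertical one.
    The triad is the eigenvector system used to orient ellipsoids.
    """

    u1: np.ndarray
    u2: np.ndarray
    u3: np.ndarray

    def __post_init__(self):
        for name in ("u1", "u2", "u3"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        U = self.matrix
        if not np.allclose(U.T @ U, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal")
        if not math.isclose(float(np.linalg.det(U)), 1.0, abs_tol=1e-9):
            raise GeometryError("frame is not right-handed (det != +1)")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix with u1, u2, u3 as columns."""
        return np.column_stack([self.u1, self.u2, self.u3])

    @staticmethod
    def identity() -> "OrientationFrame":
        return OrientationFrame(np.array([1.0, 0, 0]),
                                np.array([0, 1.0, 0]),
                                np.array([0, 0, 1.0]))


# ---------------------------------------------------------------------------
# shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Oriented ellipsoid: center, orientation frame, semi-axes (µm).

    The quadratic form ``Q = U diag(1/l1^2, 1/l2^2, 1/l3^2) U^T`` is
    symmetric positive definite; a point x is inside iff
    ``(x-c)^T Q (x-c) <= 1``.
    """

    center: np.ndarray
    frame: OrientationFrame
    semiaxes: tuple

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        ax = tuple(float(a) for a in self.semiaxes)
        if len(ax) != 3 or any(a <= 0 for a in ax):
            raise GeometryError(f"semiaxes must be three positive lengths, got {ax}")
        object.__setattr__(self, "semiaxes", ax)

    @property
    def quadratic_form(self) -> np.ndarray:
        U = self.frame.matrix
        D = np.diag([1.0 / a ** 2 for a in self.semiaxes])
        return U @ D @ U.T

    def quad_residual(self, points) -> np.ndarray:
        """(x-c)^T Q (x-c) for each point; 1 on the surface."""
        d = _as_points(points) - self.center
        Q = self.quadratic_form
        return np.einsum("ij,jk,ik->i", d, Q, d)

    def contains(self, points, tol: float = CONTAIN_TOL, strict: bool = False) -> np.ndarray:
        r = self.quad_residual(points)
        return r < 1.0 if strict else r <= 1.0 + tol

    @property
    def volume(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def aabb(self) -> "AABB":
        # extent of an oriented ellipsoid along axis e is sqrt(e^T M e),
        # M = U diag(l^2) U^T; for coordinate axes that is the row norm of
        # U scaled by the semiaxes.
        U = self.frame.matrix
        ext = np.sqrt(((U * np.asarray(self.semiaxes)) ** 2).sum(axis=1))
        return AABB(self.center - ext, self.center + ext)


@dataclass(frozen=True)
class Cone:
    """Circular cone from apex O to a base circle of radius R about P.

    Points are parameterised by height fraction h/H along the axis
    d = P - O and an angle in the basal-plane basis (u, v).
    """

    apex: np.ndarray
    base_center: np.ndarray
    base_radius: float

    def __post_init__(self):
        object.__setattr__(self, "apex", _as_point(self.apex))
        object.__setattr__(self, "base_center", _as_point(self.base_center))
        object.__setattr__(self, "base_radius", float(self.base_radius))
        if self.base_radius <= 0:
            raise GeometryError("cone base radius must be > 0")
        if self.height <= 0:
            raise GeometryError("cone apex and base center coincide")

    @property
    def axis_vector(self) -> np.ndarray:
        """d = P - O."""
        return self.base_center - self.apex

    @property
    def height(self) -> float:
        return float(np.linalg.norm(self.axis_vector))

    @property
    def basal_basis(self) -> tuple:
        """Two orthonormal vectors (u, v) spanning the base-circle plane."""
        d = self.axis_vector / self.height
        seed = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
        u = np.cross(d, seed)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v

    @property
    def volume(self) -> float:
        return math.pi * self.base_radius ** 2 * self.height / 3.0

    def contains(self, points, tol: float = CONTAIN_TOL, strict: bool = False) -> np.ndarray:
        pts = _as_points(points) - self.apex
        d = self.axis_vector
        H = self.height
        h = pts @ (d / H)            # axial coordinate in [0, H]
        radial = np.linalg.norm(pts - np.outer(h / H, d), axis=1)
        rmax = self.base_radius * h / H
        if strict:
            return (h > 0) & (h < H) & (radial < rmax)
        return (h >= -tol) & (h <= H + tol) & (radial <= rmax + tol)

    @property
    def aabb(self) -> "AABB":
        u, v = self.basal_basis
        R = self.base_radius
        # base circle extent along each coordinate axis
        ext = R * np.sqrt(u ** 2 + v ** 2)
        lo = np.minimum(self.apex, self.base_center - ext)
        hi = np.maximum(self.apex, self.base_center + ext)
        return AABB(lo, hi)


Shape = Union[Ellipsoid, Cone]


def shape_volume(shape: Shape) -> float:
    """Closed-form volume (µm³) of an ellipsoid or cone."""
    return shape.volume


# ---------------------------------------------------------------------------
# triangulated meshes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriMesh:
    """Triangulated landmark surface (vertices in µm)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise GeometryError("mesh vertices must be a non-empty (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise GeometryError("mesh must have at least one triangular face")
        if f.min() < 0 or f.max() >= len(v):
            raise GeometryError("mesh face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    @classmethod
    def load(cls, path) -> "TriMesh":
        m = _trimesh.load(str(path), force="mesh", process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))

    def save(self, path) -> None:
        m = _trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        path = str(path)
        if path.lower().endswith(".ply"):
            data = _trimesh.exchange.ply.export_ply(m, encoding="ascii")
            mode = "wb" if isinstance(data, bytes) else "w"
            with open(path, mode) as fh:
                fh.write(data)
        else:
            m.export(path)


def _point_triangle_distances(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    """(n_points, n_faces) exact distances, computed blockwise."""
    tri = mesh.triangles
    n_f = len(tri)
    out = np.empty((len(points), n_f))
    block = max(1, int(2e5) // max(n_f, 1))
    for s in range(0, len(points), block):
        chunk = points[s:s + block]
        n_c = len(chunk)
        trif = np.repeat(tri[None, :, :, :], n_c, axis=0).reshape(-1, 3, 3)
        ptsf = np.repeat(chunk, n_f, axis=0)
        closest = _trimesh.triangles.closest_point(trif, ptsf)
        d = np.linalg.norm(closest - ptsf, axis=1)
        out[s:s + n_c] = d.reshape(n_c, n_f)
    return out


def min_distance_to_mesh(p, mesh: TriMesh):
    """Minimum distance from a point to a triangulated mesh.

    Returns ``(distance, closest_point, vector)`` with
    ``vector = closest_point - p`` and ``distance = |vector|``; the
    minimum is exact over all faces.
    """
    p = _as_point(p)
    d, closest, vec = min_distances_to_mesh(p[None, :], mesh)
    return float(d[0]), closest[0], vec[0]


def min_distances_to_mesh(points, mesh: TriMesh):
    """Batched :func:`min_distance_to_mesh`; returns (dists, closests, vectors)."""
    pts = _as_points(points)
    tri = mesh.triangles
    n_f = len(tri)
    dists = np.empty(len(pts))
    closests = np.empty_like(pts)
    block = max(1, int(2e5) // max(n_f, 1))
    for s in range(0, len(pts), block):
        chunk = pts[s:s + block]
        n_c = len(chunk)
        trif = np.repeat(tri[None, :, :, :], n_c, axis=0).reshape(-1, 3, 3)
        ptsf = np.repeat(chunk, n_f, axis=0)
        closest = _trimesh.triangles.closest_point(trif, ptsf).reshape(n_c, n_f, 3)
        d = np.linalg.norm(closest - chunk[:, None, :], axis=2)
        idx = d.argmin(axis=1)
        dists[s:s + n_c] = d[np.arange(n_c), idx]
        closests[s:s + n_c] = closest[np.arange(n_c), idx]
    return dists, closests, closests - pts


# ---------------------------------------------------------------------------
# frames from landmarks
# ---------------------------------------------------------------------------

def frame_from_vectors(v_sub, v_ca3) -> OrientationFrame:
    """Frame from soma->subiculum and soma->CA3 minimum-distance vectors.

    u1 is the normalised soma->subiculum vector (transversal axis), u2 the
    normalised cross product v_sub x v_ca3 (longitudinal axis) and
    u3 = u1 x u2 (vertical axis).
    """
    v_sub = _as_point(v_sub)
    v_ca3 = _as_point(v_ca3)
    n_sub = np.linalg.norm(v_sub)
    n_ca3 = np.linalg.norm(v_ca3)
    if n_sub <= 0 or n_ca3 <= 0:
        raise GeometryError("landmark distance vectors must be non-zero")
    c = np.cross(v_sub, v_ca3)
    if np.linalg.norm(c) / (n_sub * n_ca3) < 1e-6:
        raise DegenerateFrameError(
            "subiculum and CA3 distance vectors are (anti-)parallel")
    u1 = v_sub / n_sub
    u2 = c / np.linalg.norm(c)
    u3 = np.cross(u1, u2)
    return OrientationFrame(u1, u2, u3)


def build_frame(soma, sub_mesh: TriMesh, ca3_mesh: TriMesh) -> OrientationFrame:
    """Anatomical orientation frame for a soma from the two landmark meshes."""
    _, _, v_sub = min_distance_to_mesh(soma, sub_mesh)
    _, _, v_ca3 = min_distance_to_mesh(soma, ca3_mesh)
    return frame_from_vectors(v_sub, v_ca3)


def frame_with_fallback(v_sub, v_ca3) -> OrientationFrame:
    """Like :func:`frame_from_vectors` but degeneracy-tolerant.

    When the two landmark vectors are (anti-)parallel the CA3 vector is
    replaced by the coordinate axis least aligned with the transversal
    direction, and a warning is logged.
    """
    try:
        return frame_from_vectors(v_sub, v_ca3)
    except DegenerateFrameError:
        v_sub = _as_point(v_sub)
        u1 = v_sub / np.linalg.norm(v_sub)
        axis = np.argmin(np.abs(u1))
        repl = np.zeros(3)
        repl[axis] = 1.0
        logger.warning(
            "degenerate landmark frame; replacing CA3 vector with axis %d", axis)
        return frame_from_vectors(v_sub, repl)


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """Scattered 3-D points sampled on or in a generating shape."""

    points: np.ndarray
    source_shape: Optional[Shape] = None
    role: Optional[str] = None  # axon | apical-dendrite | basal-dendrite

    def __post_init__(self):
        self.points = _as_points(self.points)

    def __len__(self):
        return len(self.points)


def ellipsoid_surface_points(e: Ellipsoid, n: int) -> PointCloud:
    """Points on the ellipsoid surface from a parametric (theta, phi) grid.

    Uses the canonical spherical parameterisation
    ``x = l1 cos(theta) sin(phi), y = l2 sin(theta) sin(phi),
    z = l3 cos(phi)`` over ``0 <= theta <= 2*pi, -pi <= phi <= 0``,
    mapped by the orientation frame and translated to the center.
    """
    if n < 4:
        raise GeometryError("need at least 4 surface points")
    n_theta = max(3, int(math.ceil(math.sqrt(n))))
    n_phi = max(3, int(math.ceil(n / n_theta)) + 1)
    theta = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
    phi = np.linspace(-math.pi, 0.0, n_phi)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    l1, l2, l3 = e.semiaxes
    local = np.stack([l1 * np.cos(T) * np.sin(P),
                      l2 * np.sin(T) * np.sin(P),
                      l3 * np.cos(P)], axis=-1).reshape(-1, 3)
    world = e.center + local @ e.frame.matrix.T
    return PointCloud(world, source_shape=e)


def cone_surface_points(c: Cone, n: int) -> PointCloud:
    """Points on the lateral cone surface on a parametric (h, theta) grid.

    Follows ``p = O + (h/H) d + R (h/H)(cos(theta) u + sin(theta) v)`` for
    ``0 <= h <= H``; the h=0 ring degenerates to the apex and the h=H ring
    is the base circle of radius R about P.
    """
    if n < 4:
        raise GeometryError("need at least 4 surface points")
    n_h = max(3, int(math.ceil(math.sqrt(n / 2))))
    n_theta = max(4, int(math.ceil(n / n_h)))
    h = np.linspace(0.0, c.height, n_h)
    theta = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
    Hgrid, T = np.meshgrid(h, theta, indexing="ij")
    u, v = c.basal_basis
    frac = (Hgrid / c.height)[..., None]
    radial = c.base_radius * frac * (np.cos(T)[..., None] * u + np.sin(T)[..., None] * v)
    pts = c.apex + frac * c.axis_vector + radial
    return PointCloud(pts.reshape(-1, 3), source_shape=c)


def fill_points(shape: Shape, voxel_side: float = DEFAULT_VOXEL_SIDE,
                rng: Optional[np.random.Generator] = None) -> PointCloud:
    """Volume-filling cloud with one point per ``voxel_side**3`` of volume.

    The point count is ``max(1, floor(V / voxel_side**3))``.  Points are
    placed on a jittered regular grid cropped to the shape interior, then
    trimmed or padded (by rejection sampling) to the exact count so the
    one-point-per-voxel bookkeeping is exact for every shape.
    """
    if voxel_side <= 0:
        raise GeometryError("voxel side must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    count = max(1, int(math.floor(shape.volume / voxel_side ** 3)))
    box = shape.aabb
    span = box.hi - box.lo
    n_cells = np.maximum(1, np.ceil(span / voxel_side).astype(int))
    step = span / n_cells
    axes = [box.lo[k] + (np.arange(n_cells[k]) + 0.5) * step[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    jitter = rng.uniform(-0.5, 0.5, size=centers.shape) * step
    pts = centers + jitter
    pts = pts[shape.contains(pts, strict=True)]
    if len(pts) > count:
        keep = np.sort(rng.choice(len(pts), size=count, replace=False))
        pts = pts[keep]
    while len(pts) < count:
        need = count - len(pts)
        extra = rng.uniform(box.lo, box.hi, size=(max(4 * need, 16), 3))
        extra = extra[shape.contains(extra, strict=True)]
        pts = np.vstack([pts, extra[:need]]) if len(extra) else pts
    return PointCloud(pts, source_shape=shape)


# ---------------------------------------------------------------------------
# convex hulls
# ---------------------------------------------------------------------------

@dataclass
class HullVolume:
    """Convex volume as half-spaces ``normal . x <= offset`` plus vertices."""

    normals: np.ndarray
    offsets: np.ndarray
    vertices: np.ndarray

    def contains(self, points, tol: float = CONTAIN_TOL) -> np.ndarray:
        pts = _as_points(points)
        return np.all(pts @ self.normals.T <= self.offsets + tol, axis=1)

    @property
    def aabb(self) -> "AABB":
        return aabb(PointCloud(self.vertices))


def convex_hull(cloud: PointCloud) -> HullVolume:
    """Convex hull of a point cloud in half-space representation."""
    pts = cloud.points if isinstance(cloud, PointCloud) else _as_points(cloud)
    if len(pts) < 4:
        raise GeometryError("convex hull needs at least 4 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate (coplanar) hull input: {exc}") from exc
    # scipy equations are [normal | d] with normal . x + d <= 0 inside
    normals = hull.equations[:, :3]
    offsets = -hull.equations[:, 3]
    return HullVolume(normals, offsets, pts[hull.vertices])


def hull_contains(hull: HullVolume, p, tol: float = CONTAIN_TOL):
    """True iff ``normal . p <= offset + tol`` for every half-space."""
    res = hull.contains(p, tol=tol)
    return bool(res[0]) if np.asarray(p).ndim == 1 else res


# ---------------------------------------------------------------------------
# axis-aligned bounding boxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AABB:
    """Axis-aligned box [lo, hi], closed on both ends."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", _as_point(self.lo))
        object.__setattr__(self, "hi", _as_point(self.hi))
        if np.any(self.lo > self.hi):
            raise GeometryError("AABB min exceeds max")

    def overlaps(self, other: "AABB") -> bool:
        return aabb_overlap(self, other)


def aabb(cloud) -> AABB:
    """Minimal bounding box of a point cloud (bounds attained by points)."""
    pts = cloud.points if isinstance(cloud, PointCloud) else _as_points(cloud)
    if len(pts) == 0:
        raise GeometryError("cannot bound an empty point set")
    return AABB(pts.min(axis=0), pts.max(axis=0))


def aabb_overlap(a: AABB, b: AABB) -> bool:
    """Closed-interval overlap on all three axes (touching boxes overlap)."""
    return bool(np.all(a.hi >= b.lo) and np.all(b.hi >= a.lo))
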