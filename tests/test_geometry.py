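"""Geometric primitives: distances, frames, clouds, hulls, boxes."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from pma.errors import DegenerateFrameError, GeometryError
from pma.geometry import (AABB, Cone, Ellipsoid, OrientationFrame, PointCloud,
                          TriMesh, aabb, aabb_overlap, cone_surface_points,
                          convex_hull, ellipsoid_surface_points, fill_points,
                          frame_from_vectors, frame_with_fallback,
                          hull_contains, min_distance_to_mesh, shape_volume)


# --------------------------------------------------------------------------
# independent point-triangle distance oracle (barycentric clamping)
# --------------------------------------------------------------------------

def _point_triangle_dist(p, a, b, c):
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return np.linalg.norm(p - (a + ab * (d1 / (d1 - d3))))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return np.linalg.norm(p - (a + ac * (d2 / (d2 - d6))))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + (c - b) * w))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return np.linalg.norm(p - (a + ab * v + ac * w))


class TestMeshDistance:
    def test_vertex_coincidence_gives_zero(self):
        m = TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        d, closest, vec = min_distance_to_mesh([1, 0, 0], m)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_foot(self):
        m = TriMesh([[-1, -1, 0], [2, -1, 0], [0, 2, 0]], [[0, 1, 2]])
        d, closest, vec = min_distance_to_mesh([0, 0, 5.0], m)
        assert d == pytest.approx(5.0)
        np.testing.assert_allclose(vec, [0, 0, -5.0], atol=1e-9)

    def test_empty_mesh_rejected(self):
        with pytest.raises(GeometryError):
            TriMesh(np.zeros((3, 3)), np.zeros((0, 3), dtype=int))

    def test_matches_per_triangle_bruteforce(self, rng):
        verts = rng.uniform(-50, 50, size=(40, 3))
        faces = rng.integers(0, 40, size=(50, 3))
        faces = faces[(faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
                      & (faces[:, 0] != faces[:, 2])]
        m = TriMesh(verts, faces)
        tri = m.triangles
        for p in rng.uniform(-80, 80, size=(25, 3)):
            d, closest, vec = min_distance_to_mesh(p, m)
            brute = min(_point_triangle_dist(p, *t) for t in tri)
            assert d == pytest.approx(brute, abs=1e-9)
            assert d == pytest.approx(np.linalg.norm(vec), abs=1e-12)
            np.testing.assert_allclose(closest - p, vec, atol=1e-12)


class TestOrientationFrame:
    def test_axis_aligned_example(self):
        f = frame_from_vectors([100, 0, 0], [-50, 20, 0])
        np.testing.assert_allclose(f.u1, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.u2, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.u3, [0, -1, 0], atol=1e-12)

    def test_orthonormal_and_right_handed_random(self, rng):
        for _ in range(1000):
            v1, v2 = rng.normal(size=3), rng.normal(size=3)
            if np.linalg.norm(np.cross(v1, v2)) < 1e-3:
                continue
            f = frame_from_vectors(v1, v2)
            U = f.matrix
            np.testing.assert_allclose(U.T @ U, np.eye(3), atol=1e-9)
            assert np.linalg.det(U) == pytest.approx(1.0, abs=1e-9)

    def test_parallel_vectors_raise_and_fallback_recovers(self):
        with pytest.raises(DegenerateFrameError):
            frame_from_vectors([1, 0, 0], [-2, 0, 0])
        f = frame_with_fallback([1, 0, 0], [-2, 0, 0])
        np.testing.assert_allclose(f.u1, [1, 0, 0], atol=1e-12)
        assert np.linalg.det(f.matrix) == pytest.approx(1.0, abs=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(GeometryError):
            OrientationFrame([1, 0, 0], [1, 0, 0], [0, 0, 1])


class TestSurfacePoints:
    def test_unit_sphere_radius(self):
        e = Ellipsoid([0, 0, 0], OrientationFrame.identity(), (1, 1, 1))
        pts = ellipsoid_surface_points(e, 100).points
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-6)

    def test_major_axis_extent(self):
        e = Ellipsoid([0, 0, 0], OrientationFrame.identity(), (2, 1, 1))
        pts = ellipsoid_surface_points(e, 400).points
        assert np.abs(pts[:, 0]).max() == pytest.approx(2.0, abs=1e-9)

    def test_quadratic_form_residual_random(self, rng):
        for _ in range(20):
            f = frame_from_vectors(rng.normal(size=3), rng.normal(size=3))
            e = Ellipsoid(rng.uniform(-100, 100, 3), f,
                          tuple(rng.uniform(5, 300, 3)))
            pts = ellipsoid_surface_points(e, 60)
            np.testing.assert_allclose(e.quad_residual(pts.points), 1.0, atol=1e-6)

    def test_cone_base_circle_and_apex(self):
        c = Cone([0, 0, 0], [0, 0, 400], 80.0)
        pts = cone_surface_points(c, 200).points
        base = pts[np.abs(pts[:, 2] - 400) < 1e-9]
        assert len(base) > 0
        np.testing.assert_allclose(
            np.linalg.norm(base[:, :2], axis=1), 80.0, atol=1e-6)
        apex = pts[np.abs(pts[:, 2]) < 1e-9]
        np.testing.assert_allclose(apex, 0.0, atol=1e-9)

    def test_cone_radius_law(self, rng):
        c = Cone(rng.uniform(-10, 10, 3), rng.uniform(100, 300, 3), 50.0)
        pts = cone_surface_points(c, 300).points
        d = c.axis_vector
        h = (pts - c.apex) @ (d / c.height)
        radial = np.linalg.norm(pts - c.apex - np.outer(h / c.height, d), axis=1)
        assert np.all(radial <= 50.0 * h / c.height + 1e-6)


class TestVolumes:
    def test_apical_cone_volume(self):
        v = shape_volume(Cone([0, 0, 0], [0, 0, 400], 80.0))
        assert v == pytest.approx(2_680_825.7, abs=0.1)
        assert round(v / 10_000) * 10_000 == 2_680_000

    def test_unit_sphere(self):
        e = Ellipsoid([0, 0, 0], OrientationFrame.identity(), (1, 1, 1))
        assert shape_volume(e) == pytest.approx(4 * math.pi / 3)

    def test_ellipsoid_closed_form(self):
        e = Ellipsoid([0, 0, 0], OrientationFrame.identity(), (100, 50, 50))
        assert shape_volume(e) == pytest.approx(1_047_197.6, abs=0.1)


class TestFillPoints:
    def test_apical_cone_has_335_points(self, rng):
        cloud = fill_points(Cone([0, 0, 0], [0, 0, 400], 80.0), rng=rng)
        assert len(cloud) == 335

    def test_subvoxel_shape_keeps_one_point(self, rng):
        e = Ellipsoid([0, 0, 0], OrientationFrame.identity(), (1, 1, 1))
        cloud = fill_points(e, rng=rng)
        assert len(cloud) == 1
        assert bool(e.contains(cloud.points, strict=True)[0])

    def test_ellipsoid_count(self, rng):
        e = Ellipsoid([0, 0, 0], OrientationFrame.identity(), (100, 50, 50))
        assert len(fill_points(e, rng=rng)) == 130

    def test_count_law_and_interior_random_shapes(self, rng):
        for _ in range(100):
            if rng.uniform() < 0.5:
                f = frame_from_vectors(rng.normal(size=3), rng.normal(size=3))
                shape = Ellipsoid(rng.uniform(-50, 50, 3), f,
                                  tuple(rng.uniform(10, 150, 3)))
            else:
                shape = Cone(rng.uniform(-50, 50, 3),
                             rng.uniform(60, 300, 3), rng.uniform(10, 120))
            cloud = fill_points(shape, rng=rng)
            expected = max(1, math.floor(shape.volume / 8000.0))
            assert len(cloud) == expected
            assert shape.contains(cloud.points, strict=True).all()


class TestHulls:
    def test_unit_cube(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                           dtype=float)
        h = convex_hull(PointCloud(corners))
        planes = np.unique(np.round(np.column_stack([h.normals, h.offsets]), 9), axis=0)
        assert len(planes) == 6
        assert ConvexHull(corners).volume == pytest.approx(1.0)
        assert h.contains(corners).all()
        assert hull_contains(h, [0.5, 0.5, 0.5])
        assert not hull_contains(h, [2.5, 0.5, 0.5])

    def test_hull_of_ellipsoid_contains_center(self, rng):
        e = Ellipsoid([5, -3, 2], OrientationFrame.identity(), (30, 20, 10))
        h = convex_hull(ellipsoid_surface_points(e, 80))
        assert hull_contains(h, [5, -3, 2])

    def test_degenerate_input_rejected(self):
        flat = np.column_stack([np.random.rand(10), np.random.rand(10),
                                np.zeros(10)])
        with pytest.raises(GeometryError):
            convex_hull(PointCloud(flat))

    def test_membership_of_input_vertices(self, rng):
        for _ in range(10):
            pts = rng.uniform(-100, 100, size=(30, 3))
            h = convex_hull(PointCloud(pts))
            assert h.contains(pts, tol=1e-7).all()

    def test_against_barycentric_oracle_on_tetrahedron(self, rng):
        verts = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0], [0, 0, 100]],
                         dtype=float)
        h = convex_hull(PointCloud(verts))
        pts = rng.uniform(-20, 120, size=(10_000, 3))
        # barycentric coordinates w.r.t. the tetrahedron
        T = (verts[1:] - verts[0]).T
        lam = np.linalg.solve(T, (pts - verts[0]).T).T
        oracle = (lam >= -1e-9).all(axis=1) & (lam.sum(axis=1) <= 1 + 1e-9)
        np.testing.assert_array_equal(h.contains(pts, tol=1e-6), oracle)


class TestAABB:
    def test_single_and_antipodal_points(self):
        b = aabb(PointCloud([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(b.lo, b.hi)
        b = aabb(PointCloud([[-1, -2, -3], [4, 5, 6]]))
        np.testing.assert_array_equal(b.lo, [-1, -2, -3])
        np.testing.assert_array_equal(b.hi, [4, 5, 6])

    def test_minimality_random(self, rng):
        pts = rng.normal(size=(500, 3))
        b = aabb(PointCloud(pts))
        np.testing.assert_array_equal(b.lo, pts.min(axis=0))
        np.testing.assert_array_equal(b.hi, pts.max(axis=0))

    def test_touching_boxes_overlap(self):
        a = AABB([0, 0, 0], [1, 1, 1])
        assert aabb_overlap(a, AABB([1, 0, 0], [2, 1, 1]))       # shared face
        assert aabb_overlap(a, AABB([0.5, 0.5, 0.5], [1.5, 1.5, 1.5]))
        assert not aabb_overlap(a, AABB([1.1, 0, 0], [2, 1, 1]))

    def test_overlap_matches_interval_oracle(self, rng):
        lo1 = rng.uniform(-5, 5, size=(10_000, 3))
        hi1 = lo1 + rng.uniform(0, 3, size=(10_000, 3))
        lo2 = rng.uniform(-5, 5, size=(10_000, 3))
        hi2 = lo2 + rng.uniform(0, 3, size=(10_000, 3))
        oracle = np.all((hi1 >= lo2) & (hi2 >= lo1), axis=1)
        got = np.array([aabb_overlap(AABB(a, b), AABB(c, d))
                        for a, b, c, d in zip(lo1, hi1, lo2, hi2)])
        np.testing.assert_array_equal(got, oracle)

    def test_invalid_boxes_rejected(self):
        with pytest.raises(GeometryError):
            AABB([1, 0, 0], [0, 1, 1])
        with pytest.raises(GeometryError):
            aabb(PointCloud(np.empty((0, 3))))
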