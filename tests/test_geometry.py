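"""Sphere geometry: fitting, projection, areas, distances, drift removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from epiboly import geometry as g

R = 592.0


def rand_sphere_points(n, rng, R=R, theta_max=np.pi):
    cos_t = rng.uniform(np.cos(theta_max), 1.0, n)
    return g.from_spherical(np.arccos(cos_t),
                            rng.uniform(-np.pi, np.pi, n), R)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class TestSphereFit:
    def test_exact_unit_sphere(self):
        rng = np.random.default_rng(0)
        pts = rand_sphere_points(100, rng, R=1.0)
        fit = g.fit_sphere_algebraic(pts)
        assert np.allclose(fit.center, 0.0, atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)

    def test_noisy_egg_radius(self):
        rng = np.random.default_rng(1)
        pts = rand_sphere_points(2000, rng) + rng.normal(0, 1.0, (2000, 3))
        fit = g.fit_sphere_algebraic(pts)
        assert fit.radius == pytest.approx(R, abs=0.5)
        assert fit.rms_residual == pytest.approx(1.0, rel=0.2)

    def test_matches_geometric_least_squares(self):
        """Algebraic fit agrees with iterative geometric minimisation."""
        rng = np.random.default_rng(2)
        pts = rand_sphere_points(500, rng, theta_max=2.0) \
            + rng.normal(0, 2.0, (500, 3))

        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        geo = least_squares(resid, x0=np.array([5.0, -5.0, 5.0, 500.0]))
        fit = g.fit_sphere_algebraic(pts)
        assert fit.radius == pytest.approx(geo.x[3], abs=0.5)
        assert np.allclose(fit.center, geo.x[:3], atol=0.5)

    def test_degenerate_coplanar(self):
        pts = np.column_stack([np.random.default_rng(3).normal(size=(20, 2)),
                               np.zeros(20)])
        with pytest.raises(ValueError):
            g.fit_sphere_algebraic(pts)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            g.fit_sphere_algebraic(np.eye(3))


class TestProjection:
    def setup_method(self):
        self.fit = g.SphereFit(center=np.zeros(3), radius=R, rms_residual=0.0)

    @pytest.mark.parametrize("xy,expected", [
        ((0.0, 0.0), (0.0, 0.0, R)),
        ((R, 0.0), (R, 0.0, 0.0)),
    ])
    def test_known_points(self, xy, expected):
        assert np.allclose(g.project_to_sphere(*xy, self.fit), expected)

    def test_radius_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            rho = R * np.sqrt(rng.uniform())
            ang = rng.uniform(-np.pi, np.pi)
            p = g.project_to_sphere(rho * np.cos(ang), rho * np.sin(ang),
                                    self.fit)
            assert np.linalg.norm(p) == pytest.approx(R, rel=1e-9)

    def test_outside_disc(self):
        with pytest.raises(ValueError):
            g.project_to_sphere(R + 1.0, 0.0, self.fit)


class TestGeodesic:
    def test_coincident_and_antipodal(self):
        p = np.array([0.0, 0.0, R])
        assert g.geodesic_distance(p, p, R) == 0.0
        assert g.geodesic_distance(p, -p, R) == pytest.approx(np.pi * R)

    def test_matches_quadrature(self):
        """Chord-free arc formula equals numerical great-circle arc length."""
        rng = np.random.default_rng(5)
        p, q = rand_sphere_points(2, rng)
        # integrate along the slerp path between p and q
        t = np.linspace(0.0, 1.0, 20001)
        ang = g.angle_between(p, q)
        path = (np.sin((1 - t))[:, None] * 0)  # placeholder replaced below
        u, v = p / R, q / R
        path = (np.sin((1 - t) * ang)[:, None] * u
                + np.sin(t * ang)[:, None] * v) / np.sin(ang)
        path *= R
        arc = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
        assert g.geodesic_distance(p, q, R) == pytest.approx(arc, rel=1e-6)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            g.geodesic_distance(np.zeros(3), np.array([1.0, 0, 0]), R)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rand_sphere_points(3, rng)
        assert g.geodesic_distance(a, c, R) <= (
            g.geodesic_distance(a, b, R) + g.geodesic_distance(b, c, R)
            + 1e-9)


def lhuilier_area(vertices, R):
    """Triangulation oracle: sum of spherical-triangle excesses (l'Huilier)."""
    u = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
    total = 0.0
    for k in range(1, len(u) - 1):
        a = g.angle_between(u[k], u[k + 1])
        b = g.angle_between(u[0], u[k + 1])
        c = g.angle_between(u[0], u[k])
        s = 0.5 * (a + b + c)
        t = np.sqrt(max(0.0, np.tan(s / 2) * np.tan((s - a) / 2)
                        * np.tan((s - b) / 2) * np.tan((s - c) / 2)))
        total += 4.0 * np.arctan(t)
    return total * R * R


class TestSphericalPolygonArea:
    def test_octant(self):
        tri = R * np.eye(3)
        assert g.spherical_polygon_area(tri, R) == \
            pytest.approx(np.pi * R**2 / 2, rel=1e-12)

    def test_planar_limit_square(self):
        s = 1.0
        sq = np.array([[s/2, s/2], [-s/2, s/2], [-s/2, -s/2], [s/2, -s/2]])
        v = np.column_stack([sq, np.sqrt(R**2 - (sq**2).sum(axis=1))])
        assert g.spherical_polygon_area(v, R) == pytest.approx(s**2, rel=1e-3)

    def test_matches_lhuilier(self):
        rng = np.random.default_rng(6)
        # convex spherical polygon: sorted azimuths around a small cap
        phi = np.sort(rng.uniform(-np.pi, np.pi, 7))
        theta = rng.uniform(0.3, 0.5, 7)
        v = g.from_spherical(theta, phi, R)
        assert g.spherical_polygon_area(v, R) == \
            pytest.approx(lhuilier_area(v, R), rel=1e-8)

    def test_orientation_and_rotation_invariance(self):
        rng = np.random.default_rng(7)
        phi = np.sort(rng.uniform(-np.pi, np.pi, 6))
        v = g.from_spherical(rng.uniform(0.4, 0.7, 6), phi, R)
        a0 = g.spherical_polygon_area(v, R)
        assert g.spherical_polygon_area(v[::-1], R) == pytest.approx(a0)
        assert g.spherical_polygon_area(np.roll(v, 2, axis=0), R) == \
            pytest.approx(a0)

    def test_cap_partition(self):
        """Meridian sectors of a cap sum to 2πR²(1−cosθ)."""
        theta_cap = 1.0
        n_sect, n_arc = 8, 600
        total = 0.0
        pole = np.array([0.0, 0.0, R])
        for k in range(n_sect):
            phi = np.linspace(2 * np.pi * k / n_sect,
                              2 * np.pi * (k + 1) / n_sect, n_arc)
            rim = g.from_spherical(np.full(n_arc, theta_cap), phi, R)
            total += g.spherical_polygon_area(np.vstack([pole, rim]), R)
        assert total == pytest.approx(g.spherical_cap_area(theta_cap, R),
                                      rel=1e-6)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            g.spherical_polygon_area(R * np.eye(3)[:2], R)


class TestPolylineDistance:
    def test_on_vertex(self):
        poly = rand_sphere_points(4, np.random.default_rng(8))
        assert g.distance_to_polyline_on_sphere(poly[2], poly, R) == \
            pytest.approx(0.0, abs=1e-9)

    def test_symmetric_point(self):
        a = g.from_spherical(0.5, -0.2, R)
        b = g.from_spherical(0.5, 0.2, R)
        mid = g.radial_project(a + b, None, R)
        p = g.from_spherical(0.3, 0.0, R)
        d = g.distance_to_polyline_on_sphere(p, np.vstack([a, b]), R)
        assert d == pytest.approx(g.geodesic_distance(p, mid, R), rel=1e-9)

    def test_dense_sampling_oracle(self):
        rng = np.random.default_rng(9)
        poly = rand_sphere_points(3, rng, theta_max=1.0)
        p = rand_sphere_points(1, rng, theta_max=1.0)[0]
        d = g.distance_to_polyline_on_sphere(p, poly, R)
        # brute force: sample each arc at 0.01 μm resolution
        best = np.inf
        for a, b in zip(poly[:-1], poly[1:]):
            ang = g.angle_between(a, b)
            n = int(np.ceil(ang * R / 0.01))
            t = np.linspace(0, 1, n)
            pts = (np.sin((1 - t) * ang)[:, None] * a
                   + np.sin(t * ang)[:, None] * b) / np.sin(ang)
            pts = g.radial_project(pts, None, R)
            best = min(best, g.geodesic_distance(p, pts, R).min())
        assert d == pytest.approx(best, abs=0.02)

    def test_empty_polyline(self):
        with pytest.raises(ValueError):
            g.distance_to_polyline_on_sphere(np.array([0, 0, R]),
                                             np.empty((0, 3)), R)

    def test_arcset_matches_reference(self):
        rng = np.random.default_rng(10)
        a = rand_sphere_points(30, rng)
        b = rand_sphere_points(30, rng)
        p = rand_sphere_points(20, rng)
        ref = g.distance_to_arcs(p, a, b, R)
        fast = g.ArcSet(a, b, R).distances(p)
        assert np.allclose(ref, fast, atol=1e-9)
        d1, c1 = g.closest_point_on_arcs(p, a, b, R)
        d2, c2 = g.ArcSet(a, b, R).closest(p)
        assert np.allclose(d1, d2, atol=1e-9)
        assert np.allclose(c1, c2, atol=1e-6)


class TestDriftRemoval:
    def test_identity_for_identical_frames(self):
        pts = rand_sphere_points(30, np.random.default_rng(11), theta_max=1.0)
        rots, corr = g.remove_rotational_drift([pts, pts], align_axis=False)
        assert np.allclose(rots[1], np.eye(3), atol=1e-12)
        assert np.allclose(corr[1], pts)

    def test_rotation_with_isotropic_growth(self):
        """5° drift + 1.1× growth: axis/angle recovered within 0.1°."""
        rng = np.random.default_rng(12)
        pts = rand_sphere_points(40, rng, theta_max=1.0)
        axis = np.array([0.2, -0.1, 0.97])
        M = rotation_matrix(axis, np.deg2rad(5.0))
        frame1 = (1.1 * pts) @ M.T
        rots, corr = g.remove_rotational_drift([pts, frame1],
                                               align_axis=False)
        angle = np.rad2deg(np.arccos((np.trace(rots[1]) - 1) / 2))
        assert angle == pytest.approx(5.0, abs=0.1)
        assert np.allclose(corr[1], 1.1 * pts, atol=1e-6)

    def test_noisy_rotation_vs_grid_search(self):
        """With 1 μm noise the angle matches an exhaustive grid search."""
        rng = np.random.default_rng(13)
        pts = rand_sphere_points(60, rng, theta_max=1.0)
        axis = np.array([0.1, 0.2, 0.97])
        true_deg = 5.0
        M = rotation_matrix(axis, np.deg2rad(true_deg))
        frame1 = (1.05 * pts) @ M.T + rng.normal(0, 1.0, pts.shape)
        rots, _ = g.remove_rotational_drift([pts, frame1], align_axis=False)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(rots[1]) - 1) / 2,
                                             -1, 1)))
        # oracle: exhaustive search over rotation angle about the true axis
        grid = np.linspace(3.0, 7.0, 2001)
        errs = [np.linalg.norm(
            (1.05 * pts) @ rotation_matrix(axis, np.deg2rad(a)).T - frame1)
            for a in grid]
        best = grid[int(np.argmin(errs))]
        assert angle == pytest.approx(best, abs=0.5)

    def test_reapplication_reproduces_input(self):
        rng = np.random.default_rng(14)
        frames = [rand_sphere_points(25, rng, theta_max=1.0)]
        for k in range(3):
            M = rotation_matrix(rng.normal(size=3), np.deg2rad(2.0 * (k + 1)))
            frames.append((frames[0] * (1 + 0.05 * (k + 1))) @ M.T)
        rots, corr = g.remove_rotational_drift(frames)
        for f, rot, c in zip(frames, rots, corr):
            assert np.allclose(c @ rot, f, atol=1e-8)

    def test_axis_alignment(self):
        rng = np.random.default_rng(15)
        pts = rand_sphere_points(30, rng, theta_max=0.5)
        M = rotation_matrix([1.0, 0, 0], 0.8)  # tip the cap over
        _, corr = g.remove_rotational_drift([pts @ M.T], align_axis=True)
        mean_dir = corr[0].mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        assert mean_dir[2] == pytest.approx(1.0, abs=1e-6)

    def test_underdetermined(self):
        with pytest.raises(ValueError):
            g.remove_rotational_drift([np.eye(3)[:2] * R])
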