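"""Geometry on and around the egg sphere.

The embryo surface is modelled as a sphere of radius ``R`` (≈592 μm for the
annual-killifish egg) centred at the origin, with the animal pole on +z after
drift correction.  Everything downstream — the particle simulation, trajectory
analytics and morphometric projections — goes through the primitives here:
algebraic sphere fitting, upper-hemisphere projection, geodesics, spherical
polygon areas, point-to-border distances and rigid rotational-drift removal.

Points are plain ``(3,)`` / ``(n, 3)`` float arrays in μm, egg-centred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereFit",
    "fit_sphere_algebraic",
    "project_to_sphere",
    "radial_project",
    "geodesic_distance",
    "angle_between",
    "spherical_coords",
    "from_spherical",
    "tangent_basis",
    "azimuthal_equidistant",
    "azimuthal_equidistant_inverse",
    "spherical_polygon_area",
    "spherical_cap_area",
    "distance_to_arcs",
    "distance_to_polyline_on_sphere",
    "closest_point_on_arcs",
    "ArcSet",
    "kabsch_rotation",
    "rotation_to_pole",
    "remove_rotational_drift",
]

EGG_RADIUS_UM = 592.0
"""Default egg sphere radius (μm), the radius used for surface projection."""


@dataclass(frozen=True)
class SphereFit:
    """Result of a least-squares sphere fit."""

    center: np.ndarray  # (3,) μm
    radius: float  # μm
    rms_residual: float  # μm, rms of |p - center| - radius

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms residual must be nonnegative")


def fit_sphere_algebraic(points: np.ndarray) -> SphereFit:
    """Fit a sphere by linear least squares on x²+y²+z²+ax+by+cz+d = 0.

    The algebraic formulation turns sphere fitting into a linear problem:
    solving for (a, b, c, d) gives center (−a/2, −b/2, −c/2) and radius
    sqrt(a²/4 + b²/4 + c²/4 − d).

    Parameters
    ----------
    points : (n, 3) array
        At least 4 non-coplanar points, μm.

    Raises
    ------
    ValueError
        If fewer than 4 points, the configuration is degenerate (coplanar),
        or the solution has non-positive squared radius.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise ValueError("need at least 4 points to fit a sphere")
    A = np.column_stack([pts, np.ones(len(pts))])
    b = -(pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) point configuration")
    a, bb, c, d = sol
    center = -0.5 * np.array([a, bb, c])
    r2 = center @ center - d
    if r2 <= 0:
        raise ValueError("degenerate fit: non-positive squared radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius,
                     rms_residual=float(np.sqrt(np.mean(resid**2))))


def project_to_sphere(x: float, y: float, sphere: SphereFit) -> np.ndarray:
    """Lift an (x, y) location to the upper (animal) hemisphere.

    Recovers the z-component from the sphere equation, i.e. the point on the
    fitted sphere with the given centred (x, y) and z ≥ center_z.  This is the
    projection used to repair noisy depth estimates from 2D segmentations.
    """
    cx, cy, cz = sphere.center
    dx, dy = x - cx, y - cy
    h2 = sphere.radius**2 - dx * dx - dy * dy
    if h2 < 0:
        raise ValueError(
            f"(x, y) lies outside the projection disc: x²+y² exceeds R²"
            f" by {-h2:.3g} μm²"
        )
    return np.array([x, y, cz + np.sqrt(h2)])


def radial_project(points: np.ndarray, center: np.ndarray | None = None,
                   R: float = EGG_RADIUS_UM) -> np.ndarray:
    """Push points radially onto the sphere |p − center| = R."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if center is not None:
        pts = pts - center
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot radially project the sphere center")
    out = pts * (R / norms)
    if center is not None:
        out = out + center
    return out.reshape(np.shape(points))


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero-length vector")
    return v / n


def angle_between(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Angle between vectors via atan2(|p×q|, p·q), stable near 0 and π."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    cross = np.cross(p, q)
    return np.arctan2(np.linalg.norm(cross, axis=-1), np.sum(p * q, axis=-1))


def geodesic_distance(p: np.ndarray, q: np.ndarray,
                      R: float = EGG_RADIUS_UM) -> np.ndarray:
    """Great-circle distance R·angle(p, q); inputs are taken as directions."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if np.any(np.linalg.norm(p, axis=-1) == 0) or \
            np.any(np.linalg.norm(q, axis=-1) == 0):
        raise ValueError("zero-length vector has no direction")
    return R * angle_between(p, q)


def spherical_coords(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi): polar angle from the animal pole (+z) and azimuth."""
    p = np.asarray(p, float)
    r = np.linalg.norm(p, axis=-1)
    if np.any(r == 0):
        raise ValueError("zero-length vector has no spherical coordinates")
    theta = np.arccos(np.clip(p[..., 2] / r, -1.0, 1.0))
    phi = np.arctan2(p[..., 1], p[..., 0])
    return theta, phi


def from_spherical(theta: np.ndarray, phi: np.ndarray,
                   R: float = EGG_RADIUS_UM) -> np.ndarray:
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    st = np.sin(theta)
    return np.stack([R * st * np.cos(phi), R * st * np.sin(phi),
                     R * np.cos(theta)], axis=-1)


def tangent_basis(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local tangent frame (e_theta, e_phi) at point(s) p on the sphere.

    e_theta points along the meridian toward the vegetal pole (increasing θ),
    e_phi east along the parallel.  At the poles the azimuth is degenerate;
    an arbitrary fixed frame is returned there.
    """
    u = _unit(np.atleast_2d(np.asarray(p, float)))
    z = np.array([0.0, 0.0, 1.0])
    e_phi = np.cross(z, u)
    n = np.linalg.norm(e_phi, axis=-1, keepdims=True)
    polar = (n[..., 0] < 1e-12)
    e_phi = np.where(polar[:, None], np.array([0.0, 1.0, 0.0]), e_phi / np.where(n == 0, 1.0, n))
    e_theta = np.cross(e_phi, u)  # toward increasing theta (vegetal-ward)
    # at the pole pick e_theta = +x
    e_theta = np.where(polar[:, None], np.array([1.0, 0.0, 0.0]), e_theta)
    if np.ndim(p) == 1:
        return e_theta[0], e_phi[0]
    return e_theta, e_phi


def azimuthal_equidistant(points: np.ndarray,
                          R: float = EGG_RADIUS_UM) -> np.ndarray:
    """Azimuthal equidistant projection about the animal pole.

    Maps a sphere point with spherical coordinates (θ, φ) to the plane point
    (R·θ·cosφ, R·θ·sinφ).  Geodesic distances from the pole are preserved
    exactly, which keeps distortion small over the animal cap where all the
    analysis happens.
    """
    theta, phi = spherical_coords(points)
    rho = R * theta
    return np.stack([rho * np.cos(phi), rho * np.sin(phi)], axis=-1)


def azimuthal_equidistant_inverse(xy: np.ndarray,
                                  R: float = EGG_RADIUS_UM) -> np.ndarray:
    xy = np.asarray(xy, float)
    rho = np.linalg.norm(xy, axis=-1)
    theta = rho / R
    phi = np.arctan2(xy[..., 1], xy[..., 0])
    return from_spherical(theta, phi, R)


def _triangle_solid_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Signed solid angle of the spherical triangle (a, b, c), unit vectors.

    Van Oosterom–Strackee: tan(Ω/2) = a·(b×c) / (1 + a·b + b·c + c·a).
    """
    num = float(a @ np.cross(b, c))
    den = 1.0 + float(a @ b) + float(b @ c) + float(c @ a)
    return 2.0 * np.arctan2(num, den)


def spherical_polygon_area(vertices: np.ndarray,
                           R: float = EGG_RADIUS_UM) -> float:
    """Area of a simple spherical polygon, by signed solid-angle summation.

    The polygon is fanned from its first vertex into spherical triangles whose
    signed solid angles (Van Oosterom–Strackee) add up to the polygon's signed
    solid angle — the spherical analogue of the planar shoelace / Green's
    theorem line integral.  The absolute value is returned so the result is
    independent of traversal orientation.
    """
    v = np.atleast_2d(np.asarray(vertices, float))
    if len(v) < 3:
        raise ValueError("a spherical polygon needs at least 3 vertices")
    u = _unit(v)
    omega = 0.0
    for k in range(1, len(u) - 1):
        omega += _triangle_solid_angle(u[0], u[k], u[k + 1])
    return abs(omega) * R * R


def spherical_cap_area(theta: float, R: float = EGG_RADIUS_UM) -> float:
    """Closed-form area 2πR²(1−cosθ) of the polar cap of half-angle θ."""
    return 2.0 * np.pi * R * R * (1.0 - np.cos(theta))


def distance_to_arcs(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                     R: float = EGG_RADIUS_UM) -> np.ndarray:
    """Geodesic distance from point(s) p to each great-circle arc (a_i, b_i).

    Vectorised over arcs and over points: ``p`` may be (3,) or (m, 3); ``a``
    and ``b`` are (k, 3).  Returns (k,) or (m, k) distances in μm.
    """
    P = _unit(np.atleast_2d(np.asarray(p, float)))  # (m,3)
    A = _unit(np.atleast_2d(np.asarray(a, float)))  # (k,3)
    B = _unit(np.atleast_2d(np.asarray(b, float)))
    n = np.cross(A, B)  # (k,3) great-circle normals
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    degen = nn[:, 0] < 1e-14  # a ≈ ±b: arc degenerates to endpoints
    n_hat = np.where(degen[:, None], 0.0, n / np.where(nn == 0, 1.0, nn))

    sin_xt = P @ n_hat.T  # (m,k) sine of cross-track angle
    # foot of the perpendicular lies within the arc iff it is on the same
    # side of both endpoint meridians:
    # (A×Pf)·n̂ ≥ 0 and (Pf×B)·n̂ ≥ 0 with Pf = P − (P·n̂)n̂
    Pf = P[:, None, :] - sin_xt[:, :, None] * n_hat[None, :, :]  # (m,k,3)
    cross_A_Pf = np.cross(np.broadcast_to(A[None, :, :], Pf.shape), Pf)
    cross_Pf_B = np.cross(Pf, np.broadcast_to(B[None, :, :], Pf.shape))
    inside = (np.einsum("mkc,kc->mk", cross_A_Pf, n_hat) >= 0) & (
        np.einsum("mkc,kc->mk", cross_Pf_B, n_hat) >= 0)

    d_perp = R * np.arcsin(np.clip(np.abs(sin_xt), 0.0, 1.0))
    d_a = R * angle_between(P[:, None, :], A[None, :, :])
    d_b = R * angle_between(P[:, None, :], B[None, :, :])
    d_end = np.minimum(d_a, d_b)
    out = np.where(inside & ~degen[None, :], d_perp, d_end)
    if np.ndim(p) == 1:
        return out[0]
    return out


def closest_point_on_arcs(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                          R: float = EGG_RADIUS_UM) -> tuple[np.ndarray, np.ndarray]:
    """Closest surface point on a set of arcs, per query point.

    Returns (distances (m,), closest points (m, 3)); used to direct the
    border-attraction force toward the nearest point of an EVL cell border.
    """
    P = np.atleast_2d(np.asarray(p, float))
    d = distance_to_arcs(P, a, b, R)  # (m,k)
    k_best = np.argmin(d, axis=1)
    A = _unit(np.atleast_2d(np.asarray(a, float)))[k_best]  # (m,3)
    B = _unit(np.atleast_2d(np.asarray(b, float)))[k_best]
    Pu = _unit(P)
    n = np.cross(A, B)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    degen = nn[:, 0] < 1e-14
    n_hat = n / np.where(nn == 0, 1.0, nn)
    pf = Pu - np.sum(Pu * n_hat, axis=-1, keepdims=True) * n_hat
    npf = np.linalg.norm(pf, axis=-1, keepdims=True)
    pf_ok = npf[:, 0] > 1e-14
    pf = pf / np.where(npf == 0, 1.0, npf)
    on_arc = (np.sum(np.cross(A, pf) * n_hat, axis=-1) >= 0) & (
        np.sum(np.cross(pf, B) * n_hat, axis=-1) >= 0) & pf_ok & ~degen
    da = angle_between(Pu, A)
    db = angle_between(Pu, B)
    endpoint = np.where((da <= db)[:, None], A, B)
    best = np.where(on_arc[:, None], pf, endpoint) * R
    dmin = d[np.arange(len(P)), k_best]
    if np.ndim(p) == 1:
        return dmin[0], best[0]
    return dmin, best


def distance_to_polyline_on_sphere(p: np.ndarray, polyline: np.ndarray,
                                   R: float = EGG_RADIUS_UM,
                                   closed: bool = False) -> float:
    """Minimum geodesic distance from p to a polyline of great-circle arcs."""
    poly = np.atleast_2d(np.asarray(polyline, float))
    if len(poly) == 0:
        raise ValueError("empty polyline")
    if len(poly) == 1:
        return float(geodesic_distance(p, poly[0], R))
    a = poly[:-1]
    b = poly[1:]
    if closed:
        a = np.vstack([a, poly[-1]])
        b = np.vstack([b, poly[0]])
    return float(np.min(distance_to_arcs(p, a, b, R)))


class ArcSet:
    """Precomputed great-circle arc set for fast distance queries.

    Equivalent to :func:`distance_to_arcs` / :func:`closest_point_on_arcs`
    but with per-arc frames precomputed, so repeated queries (every
    integration step of the border-attraction force, histogramming of
    thousands of distance samples) reduce to three matrix products.

    Each arc (a, b) gets an orthonormal in-plane basis (A, C) with
    C ⊥ A in the arc's plane; a query direction P has in-plane coordinates
    (u, v) = (P·A, P·C) and lies over the arc iff v ≥ 0 and
    v·cosΔ − u·sinΔ ≤ 0, where Δ is the arc's angular span.
    """

    def __init__(self, a: np.ndarray, b: np.ndarray, R: float = EGG_RADIUS_UM):
        A = _unit(np.atleast_2d(np.asarray(a, float)))
        B = _unit(np.atleast_2d(np.asarray(b, float)))
        self.R = float(R)
        n = np.cross(A, B)
        nn = np.linalg.norm(n, axis=-1, keepdims=True)
        self.degen = nn[:, 0] < 1e-14
        self.n_hat = n / np.where(nn == 0, 1.0, nn)
        C = B - np.sum(B * A, axis=-1, keepdims=True) * A
        cn = np.linalg.norm(C, axis=-1, keepdims=True)
        self.C = C / np.where(cn == 0, 1.0, cn)
        self.A, self.B = A, B
        delta = angle_between(A, B)
        self.cosd, self.sind = np.cos(delta), np.sin(delta)

    def distances(self, p: np.ndarray) -> np.ndarray:
        """(m, k) geodesic distances from each point to each arc."""
        P = _unit(np.atleast_2d(np.asarray(p, float)))
        return self._dist(P)[0]

    def _dist(self, P: np.ndarray):
        u = P @ self.A.T                      # (m,k)
        v = P @ self.C.T
        sin_xt = P @ self.n_hat.T
        inside = (v >= 0) & (v * self.cosd - u * self.sind <= 0) \
            & ~self.degen[None, :]
        d_perp = self.R * np.arcsin(np.clip(np.abs(sin_xt), 0.0, 1.0))
        cos_pa = np.clip(u, -1.0, 1.0)
        cos_pb = np.clip(P @ self.B.T, -1.0, 1.0)
        d_end = self.R * np.arccos(np.maximum(cos_pa, cos_pb))
        return np.where(inside, d_perp, d_end), (u, v, sin_xt, inside, cos_pa, cos_pb)

    def min_distance(self, p: np.ndarray) -> np.ndarray:
        """Minimum geodesic distance to the arc set, per query point."""
        d = self.distances(p)
        out = d.min(axis=1)
        return out if np.ndim(p) > 1 else out[0]

    def closest(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(distances (m,), closest surface points (m, 3))."""
        P = _unit(np.atleast_2d(np.asarray(p, float)))
        d, (u, v, sin_xt, inside, cos_pa, cos_pb) = self._dist(P)
        k = np.argmin(d, axis=1)
        m = np.arange(len(P))
        foot = u[m, k, None] * self.A[k] + v[m, k, None] * self.C[k]
        fn = np.linalg.norm(foot, axis=-1, keepdims=True)
        foot = foot / np.where(fn < 1e-14, 1.0, fn)
        endpoint = np.where((cos_pa[m, k] >= cos_pb[m, k])[:, None],
                            self.A[k], self.B[k])
        use_foot = inside[m, k] & (fn[:, 0] >= 1e-14)
        best = np.where(use_foot[:, None], foot, endpoint) * self.R
        dmin = d[m, k]
        if np.ndim(p) == 1:
            return dmin[0], best[0]
        return dmin, best


def kabsch_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Proper rotation matrix best mapping src directions onto dst.

    Rotation-only orthogonal Procrustes (no translation, no scaling): both
    clouds are radially normalised first, so pure isotropic growth between
    frames does not contaminate the recovered rotation.
    """
    u = _unit(np.atleast_2d(np.asarray(src, float)))
    v = _unit(np.atleast_2d(np.asarray(dst, float)))
    if len(u) < 3:
        raise ValueError("need at least 3 corresponded points")
    H = u.T @ v
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rotation_to_pole(v: np.ndarray) -> np.ndarray:
    """Rotation taking direction v to +z (minimal-angle rotation)."""
    u = _unit(np.asarray(v, float))
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(u @ z)
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    ang = np.arctan2(s, c)
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def remove_rotational_drift(frames: list[np.ndarray],
                            align_axis: bool = True
                            ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Remove per-frame rigid rotation from tracked point clouds.

    Eggs imaged inside the chorion can rotate slowly in the perivitelline
    space while the tissue itself grows.  Because tissue growth on the egg is
    radial/tangential scaling of directions-from-centre, normalising each
    cloud to unit vectors isolates the rigid rotation, which is then removed
    by rotation-only Kabsch against the first frame.  Optionally the whole
    sequence is re-oriented so the animal–vegetal axis (mean direction of the
    first frame's cloud) lies on +z.

    Parameters
    ----------
    frames : list of (n, 3) arrays
        Corresponding tracked points per frame (same identity order).
    align_axis : bool
        Also rotate frame 0's mean direction onto +z.

    Returns
    -------
    rotations : list of (3, 3) arrays
        Rotation applied to each frame (corrected = points @ rot.T).
    corrected : list of (n, 3) arrays
    """
    if not frames:
        raise ValueError("no frames given")
    ref = np.atleast_2d(np.asarray(frames[0], float))
    if len(ref) < 3:
        raise ValueError("need at least 3 corresponded points per frame")
    Q = rotation_to_pole(_unit(ref).mean(axis=0)) if align_axis else np.eye(3)
    rotations: list[np.ndarray] = []
    corrected: list[np.ndarray] = []
    for f in frames:
        f = np.atleast_2d(np.asarray(f, float))
        if len(f) != len(ref):
            raise ValueError("frames must contain the same tracked points")
        Rf = kabsch_rotation(f, ref)
        M = Q @ Rf
        rotations.append(M)
        corrected.append(f @ M.T)
    return rotations, corrected
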