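"""Three-force simulator: forces, border advance, divisions, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiboly import geometry as g
from epiboly import metrics as mtr
from epiboly import synthetic as syn
from epiboly import tracks as trk
from epiboly.mesh import EVLMesh
from epiboly.params import ATTRACTION_SCALE, SimParams
from epiboly.simulate import (DCLPopulation, Simulation, apply_divisions,
                              barycentric_weights, advance_border,
                              evl_spring_energy, evl_spring_forces,
                              run_simulation)

R = 592.0


def make_pop(positions, radius=15.0, schedule=()):
    n = len(positions)
    return DCLPopulation(np.arange(n), np.asarray(positions, float),
                         np.full(n, radius), np.zeros(n, bool),
                         list(schedule))


class TestSpringForces:
    def test_rest_configuration_zero_force(self, small_mesh):
        f = evl_spring_forces(small_mesh, U_0=0.3)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_single_stretched_edge_hooke_pair(self):
        """One stretched edge: equal/opposite tangential Hooke forces."""
        # an equatorial 3-cycle "cell" far from the poles
        v = g.from_spherical(np.array([1.5, 1.5, 1.4]),
                             np.array([0.0, 0.05, 0.025]), R)
        m = EVLMesh(vertices=v, cells=[[0, 1, 2]],
                    is_border=np.zeros(3, bool), R=R)
        delta = 2.0
        stretched = v.copy()
        d01 = (v[1] - v[0]) / np.linalg.norm(v[1] - v[0])
        # move vertex 1 along the 0-1 chord; springs 1-2, 0-2 also change,
        # so isolate spring 0-1 by zeroing the others' contribution
        m.rest_lengths = np.linalg.norm(
            stretched[m.springs[:, 0]] - stretched[m.springs[:, 1]], axis=1)
        edge01 = np.all(np.sort(m.springs, axis=1) == [0, 1], axis=1)
        m.rest_lengths[edge01] -= delta
        U0 = 0.7
        f = evl_spring_forces(m, U0, positions=stretched)
        chord = U0 * delta * d01
        n0 = v[0] / np.linalg.norm(v[0])
        n1 = v[1] / np.linalg.norm(v[1])
        exp0 = chord - (chord @ n0) * n0
        exp1 = -chord + (chord @ n1) * n1
        assert np.allclose(f[0], exp0, atol=1e-9)
        assert np.allclose(f[1], exp1, atol=1e-9)
        assert np.allclose(f[2], 0.0, atol=1e-9)

    def test_matches_numerical_gradient(self, small_mesh):
        """Forces equal −∇U (central differences), tangentially projected."""
        rng = np.random.default_rng(21)
        m = small_mesh.copy()
        pos = g.radial_project(
            m.vertices + rng.normal(0, 3.0, m.vertices.shape), None, R)
        U0 = 0.4
        f = evl_spring_forces(m, U0, positions=pos)
        h = 1e-4
        num = np.zeros_like(pos)
        for i in range(min(6, len(pos))):  # spot-check a handful of vertices
            for c in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, c] += h
                pm[i, c] -= h
                num[i, c] = -(evl_spring_energy(m, U0, pp)
                              - evl_spring_energy(m, U0, pm)) / (2 * h)
            n_hat = pos[i] / np.linalg.norm(pos[i])
            num[i] -= (num[i] @ n_hat) * n_hat
            assert np.allclose(f[i], num[i], rtol=1e-5, atol=1e-8)

    def test_coincident_endpoints_raise(self, small_mesh):
        pos = small_mesh.vertices.copy()
        i, j = small_mesh.springs[0]
        pos[j] = pos[i]
        with pytest.raises(ValueError):
            evl_spring_forces(small_mesh, 0.1, positions=pos)


class TestAdvanceBorder:
    def test_equator_vertex_moves_along_meridian(self):
        v = np.array([[R, 0.0, 0.0], [0.0, 0.0, R]])
        m = EVLMesh(vertices=v, cells=[], is_border=np.array([True, False]),
                    springs=np.empty((0, 2), int), rest_lengths=np.empty(0),
                    spring_weights=np.empty(0), R=R)
        V0, dt = 2.0, 0.5
        out = advance_border(m, V0, dt)
        theta, phi = g.spherical_coords(out.vertices[0])
        assert theta == pytest.approx(np.pi / 2 + V0 * dt / R, rel=1e-12)
        assert phi == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.vertices[1], v[1])  # bulk untouched

    def test_cumulative_arc(self):
        v = g.from_spherical(np.array([0.8]), np.array([0.3]), R)
        m = EVLMesh(vertices=v, cells=[], is_border=np.array([True]),
                    springs=np.empty((0, 2), int), rest_lengths=np.empty(0),
                    spring_weights=np.empty(0), R=R)
        V0, dt, n = 1.5, 0.25, 200
        for _ in range(n):
            m = advance_border(m, V0, dt)
        theta, _ = g.spherical_coords(m.vertices[0])
        assert (theta - 0.8) * R == pytest.approx(n * V0 * dt, rel=1e-6)

    def test_zero_speed_no_change(self, small_mesh):
        out = advance_border(small_mesh, 0.0, 1.0)
        assert np.array_equal(out.vertices, small_mesh.vertices)


class TestBarycentric:
    tri2 = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 3.0]])

    def test_vertex_and_centroid(self):
        assert np.allclose(barycentric_weights(self.tri2[0], self.tri2),
                           [1, 0, 0])
        assert np.allclose(
            barycentric_weights(self.tri2.mean(axis=0), self.tri2),
            [1 / 3] * 3)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_identity(self, seed):
        rng = np.random.default_rng(seed)
        tri = rng.normal(size=(3, 3)) * 100
        if abs(np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))) < 1:
            return
        w = rng.dirichlet(np.ones(3))
        p = w @ tri
        gam = barycentric_weights(p, tri)
        assert gam.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(gam @ tri, p, atol=1e-8)

    def test_degenerate_triangle(self):
        with pytest.raises(ValueError):
            barycentric_weights(np.zeros(2),
                                np.array([[0, 0], [1, 1], [2, 2.0]]))


class TestAttraction:
    def test_gradient_of_gaussian_well(self, small_mesh):
        """Step direction/magnitude match −∇ of U_2·exp(−d²/(2a_2²))."""
        from epiboly.simulate import _attraction_forces

        arcs_ab = small_mesh.border_arcs()
        arcset = g.ArcSet(*arcs_ab, R)
        rng = np.random.default_rng(31)
        pos = syn.place_dcl_uniform(20, R, 0.9, rng)
        U2, a2 = 0.3, 15.0
        f = _attraction_forces(pos, arcset, U2, a2, R)
        # numerical gradient of the potential along the surface
        h = 1e-3
        for p, fp in zip(pos[:8], f[:8]):
            e_t, e_p = g.tangent_basis(p)
            num = np.zeros(3)
            for e in (e_t, e_p):
                dp = arcset.min_distance(
                    g.radial_project(p + h * e, None, R)[None])[0]
                dm = arcset.min_distance(
                    g.radial_project(p - h * e, None, R)[None])[0]
                Up = -U2 * ATTRACTION_SCALE * np.exp(-dp**2 / (2 * a2**2))
                Um = -U2 * ATTRACTION_SCALE * np.exp(-dm**2 / (2 * a2**2))
                num += -(Up - Um) / (2 * h) * e
            assert np.allclose(fp, num, atol=2e-3 * max(1.0, np.linalg.norm(num)))


class TestDivisions:
    def test_radius_ratio_exact(self):
        pop = make_pop([[0, 0, R]], radius=10.0, schedule=[(1.0, 0)])
        out = apply_divisions(pop, 1.0, np.random.default_rng(0), R)
        assert out.n == 2
        assert np.allclose(out.radii, 10.0 * 0.5 ** (1 / 3))
        assert out.has_divided.all()

    def test_empty_schedule_noop(self):
        pop = make_pop([[0, 0, R]])
        out = apply_divisions(pop, 100.0, np.random.default_rng(0), R)
        assert out.n == 1
        assert not out.has_divided.any()

    def test_full_schedule_doubles_count(self):
        rng = np.random.default_rng(41)
        pos = syn.place_dcl_uniform(25, R, 1.0, rng)
        sched = [(float(t), i) for i, t in enumerate(rng.uniform(0, 10, 25))]
        pop = make_pop(pos, schedule=sched)
        out = apply_divisions(pop, 11.0, rng, R)
        assert out.n == 50
        assert len(np.unique(out.ids)) == 50

    def test_daughter_separation(self):
        pop = make_pop([[0, 0, R]], radius=12.0, schedule=[(0.5, 0)])
        out = apply_divisions(pop, 1.0, np.random.default_rng(2), R)
        sep = g.geodesic_distance(out.positions[0], out.positions[1], R)
        assert sep == pytest.approx(12.0, rel=0.01)

    def test_double_division_rejected(self):
        with pytest.raises(ValueError):
            make_pop([[0, 0, R]], schedule=[(1.0, 0), (2.0, 0)])


class TestIntegration:
    def test_all_zero_dynamics_static(self, small_mesh, small_pop):
        p = SimParams(U_0=0, V_0=0, U_1=0, U_2=0, sigma=0, drag=0,
                      n_frames=4, seed=3)
        tracks = run_simulation(p, small_mesh, small_pop)
        f0 = trk.positions(tracks, frame=0)
        for f in range(1, 4):
            assert np.allclose(trk.positions(tracks, frame=f), f0)

    def test_on_sphere_every_frame(self, small_mesh, small_pop):
        p = SimParams(n_frames=5, seed=4)
        tracks = run_simulation(p, small_mesh, small_pop)
        r = np.linalg.norm(tracks[["x", "y", "z"]].to_numpy(), axis=1)
        assert np.abs(r - R).max() < 1e-6 * R

    def test_seed_reproducibility(self, small_mesh, small_pop):
        p = SimParams(n_frames=4, seed=9)
        t1 = run_simulation(p, small_mesh, small_pop)
        t2 = run_simulation(p, small_mesh, small_pop)
        assert t1.equals(t2)

    def test_pure_advection_keeps_barycentric_coords(self, small_mesh):
        """drag=1, no noise/forces: particles ride the deforming EVL."""
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(51)
        pos = syn.place_dcl_uniform(15, R, 0.8, rng)
        pop = make_pop(pos)
        p = SimParams(U_1=0, U_2=0, sigma=0, drag=1.0, n_frames=5, seed=5)
        tracks = run_simulation(p, small_mesh, pop)

        def coords(frame):
            evl = trk.positions(tracks, frame=frame, layer="EVL_vertex")
            dcl = trk.positions(tracks, frame=frame, layer="DCL")
            xy = g.azimuthal_equidistant(evl, R)
            pxy = g.azimuthal_equidistant(dcl, R)
            tri = Delaunay(xy)
            s = tri.find_simplex(pxy)
            out = []
            for k, pq in enumerate(pxy):
                T = tri.transform[s[k]]
                b2 = T[:2, :] @ (pq - T[2, :])
                out.append((tuple(sorted(tri.simplices[s[k]])),
                            np.append(b2, 1 - b2.sum())))
            return out

        c0, c4 = coords(0), coords(4)
        same_tri = [a[0] == b[0] for a, b in zip(c0, c4)]
        # most particles stay in their triangle with near-constant weights
        assert np.mean(same_tri) > 0.7
        drifts = [np.abs(a[1] - b[1]).max()
                  for a, b, s in zip(c0, c4, same_tri) if s]
        assert np.median(drifts) < 0.05

    def test_energy_non_increasing_without_driving(self, small_mesh):
        rng = np.random.default_rng(52)
        m = small_mesh.copy()
        m.vertices = g.radial_project(
            m.vertices + rng.normal(0, 4.0, m.vertices.shape), None, R)
        pop = make_pop(syn.place_dcl_uniform(5, R, 0.8, rng))
        p = SimParams(V_0=0, sigma=0, U_1=0, U_2=0, drag=0, n_frames=6,
                      seed=6)
        s = Simulation(p, m, pop)
        energies = [evl_spring_energy(s.state.mesh, p.U_0)]
        for _ in range(5):
            s.refresh_frame_geometry()
            for _ in range(p.steps_per_frame):
                s.step()
            energies.append(evl_spring_energy(s.state.mesh, p.U_0))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))
        assert energies[-1] < energies[0]

    def test_first_order_dt_convergence(self, small_mesh, small_pop):
        """Halving dt changes a deterministic run by O(dt)."""
        def final(dt):
            p = SimParams(sigma=0, dt=dt, n_frames=3, seed=7)
            tracks = run_simulation(p, small_mesh, small_pop)
            return trk.positions(tracks, frame=2, layer="DCL")

        e1 = np.linalg.norm(final(1.0) - final(0.25), axis=1).max()
        e2 = np.linalg.norm(final(0.5) - final(0.25), axis=1).max()
        assert e2 < e1  # error shrinks with dt
        assert e1 < 1.0  # and is small in absolute terms (μm)

    def test_sigma_only_diffusion(self):
        """Noise-only ensemble: MSD slope/4 recovers the configured D."""
        n = 300
        rng = np.random.default_rng(53)
        pos = syn.place_dcl_uniform(n, R, 0.5, rng)
        pop = make_pop(pos, radius=1.0)
        mesh = syn.make_evl_tessellation(8, R, 1.2, seed=8)
        p = SimParams(U_0=0, V_0=0, U_1=0, U_2=0, drag=0, sigma=2.0e4,
                      n_frames=30, seed=10)
        tracks = run_simulation(p, mesh, pop)
        _, arr = trk.track_matrix(tracks, "DCL")
        fit = mtr.fit_diffusion(mtr.msd(arr, max_lag=10),
                                dt=p.frame_interval)
        assert fit.D_auto == pytest.approx(p.D_noise, rel=0.1)

    def test_instability_detection(self, small_mesh):
        rng = np.random.default_rng(55)
        pop = make_pop(syn.place_dcl_uniform(30, R, 0.6, rng), radius=80.0)
        p = SimParams(U_1=1e6, n_frames=3, seed=11)
        with pytest.raises(RuntimeError, match="instability"):
            run_simulation(p, small_mesh, pop)

    def test_dcl_count_doubles_with_full_schedule(self, small_mesh):
        rng = np.random.default_rng(54)
        pos = syn.place_dcl_uniform(20, R, 0.8, rng)
        sched = syn.make_division_schedule(np.arange(20), (5.0, 25.0), rng)
        pop = DCLPopulation(np.arange(20), pos, np.full(20, 15.0),
                            np.zeros(20, bool), sched)
        p = SimParams(n_frames=5, seed=12)
        tracks = run_simulation(p, small_mesh, pop)
        dcl = tracks[tracks.layer == "DCL"]
        counts = dcl.groupby("frame").size()
        assert counts.iloc[0] == 20
        assert counts.iloc[-1] == 40
        assert counts.is_monotonic_increasing
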