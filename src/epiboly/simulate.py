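"""The three-force model of deep-cell spreading on the egg sphere.

Two coupled particle systems, integrated with overdamped (unit-mobility)
forward Euler steps and re-projection onto the sphere:

* **EVL vertices** — bulk vertices relax under harmonic edge and
  opposite-vertex springs; free-border (margin) vertices advance at constant
  speed ``V_0`` along their meridian toward the vegetal pole, stretching the
  network and driving epiboly.
* **DCL particles** — soft spheres under (i) overlap repulsion of amplitude
  ``U_1``, (ii) a Gaussian attraction well of amplitude ``U_2`` and length
  ``a_2`` centred on the EVL cell borders, (iii) advection by the local EVL
  velocity field weighted by ``drag`` through barycentric interpolation on
  the Delaunay triangulation of EVL vertices, and (iv) tangential Gaussian
  noise setting the autonomous diffusion.  Cells divide once each at
  scheduled times, daughters keeping (1/2)^(1/3) of the parent radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from . import geometry as geom
from .mesh import EVLMesh
from .params import ATTRACTION_SCALE, SimParams

log = logging.getLogger(__name__)

__all__ = [
    "DCLPopulation", "SimState", "evl_spring_forces", "evl_spring_energy",
    "advance_border",
    "barycentric_weights", "apply_divisions", "dcl_step_displacement",
    "Simulation", "run_simulation",
]


@dataclass
class DCLPopulation:
    """Deep-cell particles: positions, radii and the division schedule."""

    ids: np.ndarray                 # (m,) int
    positions: np.ndarray           # (m, 3) μm
    radii: np.ndarray               # (m,) μm
    has_divided: np.ndarray         # (m,) bool
    division_schedule: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, int)
        self.positions = np.asarray(self.positions, float)
        self.radii = np.asarray(self.radii, float)
        self.has_divided = np.asarray(self.has_divided, bool)
        if np.any(self.radii <= 0):
            raise ValueError("DCL radii must be positive")
        sched_ids = [i for _, i in self.division_schedule]
        if len(sched_ids) != len(set(sched_ids)):
            raise ValueError("a DCL cell can only divide once: "
                             "duplicate id in division schedule")
        self.division_schedule = sorted(self.division_schedule)

    @property
    def n(self) -> int:
        return len(self.ids)

    def copy(self) -> "DCLPopulation":
        return DCLPopulation(self.ids.copy(), self.positions.copy(),
                             self.radii.copy(), self.has_divided.copy(),
                             list(self.division_schedule))


@dataclass
class SimState:
    """Snapshot of the coupled system."""
    time: float
    mesh: EVLMesh
    pop: DCLPopulation
    evl_velocities: np.ndarray | None = None  # (n_v, 3) μm/min


# ---------------------------------------------------------------------------
# EVL mechanics
# ---------------------------------------------------------------------------

def evl_spring_forces(mesh: EVLMesh, U_0: float,
                      positions: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex harmonic spring force, projected to the tangent plane.

    The elastic energy is Σ (U_0·w/2)(|r_i − r_j| − L_ij)² over edge and
    opposite-vertex springs; the returned array is −∂U/∂r_i with the radial
    component removed (vertices are confined to the sphere).
    """
    pos = mesh.vertices if positions is None else positions
    i, j = mesh.springs[:, 0], mesh.springs[:, 1]
    d = pos[i] - pos[j]
    L = np.linalg.norm(d, axis=1)
    if np.any(L < 1e-12):
        raise ValueError("coincident spring endpoints: direction undefined")
    f = -(U_0 * mesh.spring_weights * (L - mesh.rest_lengths) / L)[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    # tangential projection
    n_hat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    forces -= np.sum(forces * n_hat, axis=1, keepdims=True) * n_hat
    return forces


def evl_spring_energy(mesh: EVLMesh, U_0: float,
                      positions: np.ndarray | None = None) -> float:
    """Total elastic energy Σ (U_0·w/2)(|r_i − r_j| − L_ij)² of the net."""
    pos = mesh.vertices if positions is None else positions
    d = pos[mesh.springs[:, 0]] - pos[mesh.springs[:, 1]]
    L = np.linalg.norm(d, axis=1)
    return float(np.sum(0.5 * U_0 * mesh.spring_weights
                        * (L - mesh.rest_lengths) ** 2))


def advance_border(mesh: EVLMesh, V_0: float, dt: float) -> EVLMesh:
    """Move free-border vertices V_0·dt along their meridians, vegetal-ward.

    Each margin vertex advances by polar angle V_0·dt/R at fixed azimuth (an
    exact arc step, so cumulative advance is n·V_0·dt).  Vertices at the
    vegetal pole have no meridian direction; they are clamped there.
    """
    out = mesh.copy()
    if V_0 == 0.0 or not np.any(mesh.is_border):
        return out
    b = mesh.is_border
    theta, phi = geom.spherical_coords(out.vertices[b])
    theta_new = theta + V_0 * dt / mesh.R
    if np.any(theta_new > np.pi):
        log.warning("border vertex reached the vegetal pole; clamping")
        theta_new = np.minimum(theta_new, np.pi)
    out.vertices[b] = geom.from_spherical(theta_new, phi, mesh.R)
    return out


# ---------------------------------------------------------------------------
# Barycentric interpolation (the drag coupling)
# ---------------------------------------------------------------------------

def barycentric_weights(p: np.ndarray, triangle: np.ndarray) -> np.ndarray:
    """Barycentric coordinates γ of p in a triangle (2D, or 3D in-plane).

    Solves the linear reconstruction p = Σ γ_k r_k with Σ γ_k = 1.  For 3D
    inputs the computation happens in the triangle's own plane after
    projecting p onto it.
    """
    tri = np.asarray(triangle, float)
    p = np.asarray(p, float)
    if tri.shape == (3, 3):
        e1 = tri[1] - tri[0]
        e2 = tri[2] - tri[0]
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ValueError("degenerate triangle")
        # in-plane 2D coordinates
        u = e1 / np.linalg.norm(e1)
        w = np.cross(n / nn, u)
        T = np.column_stack([(tri - tri[0]) @ u, (tri - tri[0]) @ w]).T  # 2×3
        q = np.array([(p - tri[0]) @ u, (p - tri[0]) @ w])
    elif tri.shape == (3, 2):
        T = tri.T
        q = p
    else:
        raise ValueError("triangle must be (3, 2) or (3, 3)")
    M = np.vstack([T, np.ones(3)])
    rhs = np.append(q, 1.0)
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("degenerate triangle")
    return np.linalg.solve(M, rhs)


class _DragField:
    """Barycentric lookup of EVL vertex displacements.

    Delaunay triangulation of the EVL vertices on the animal-pole azimuthal
    equidistant projection, rebuilt once per output frame; weights are
    recomputed for every particle at every step.  Particles falling outside
    the triangulation (just beyond the margin) fall back to inverse-distance
    weights over the three nearest vertices and are counted in ``n_fallback``.
    """

    def __init__(self, evl_positions: np.ndarray, R: float):
        self.R = R
        self.xy = geom.azimuthal_equidistant(evl_positions, R)
        self.tri = Delaunay(self.xy)
        self.kdt = cKDTree(self.xy)
        self.n_fallback = 0

    def interpolate(self, particles: np.ndarray,
                    vertex_vectors: np.ndarray) -> np.ndarray:
        """Σ γ_k · vertex_vectors[k] over each particle's enclosing triangle."""
        pxy = geom.azimuthal_equidistant(particles, self.R)
        simp = self.tri.find_simplex(pxy)
        out = np.zeros((len(pxy), 3))
        inside = simp >= 0
        if np.any(inside):
            s = simp[inside]
            verts = self.tri.simplices[s]                       # (m,3)
            Tinv = self.tri.transform[s]                        # (m,3,2)
            b2 = np.einsum("mij,mj->mi", Tinv[:, :2, :],
                           pxy[inside] - Tinv[:, 2, :])
            gamma = np.column_stack([b2, 1.0 - b2.sum(axis=1)])  # (m,3)
            out[inside] = np.einsum("mk,mkc->mc", gamma,
                                    vertex_vectors[verts])
        if np.any(~inside):
            self.n_fallback += int(np.sum(~inside))
            dist, idx = self.kdt.query(pxy[~inside], k=3)
            w = 1.0 / np.maximum(dist, 1e-9)
            w /= w.sum(axis=1, keepdims=True)
            out[~inside] = np.einsum("mk,mkc->mc", w, vertex_vectors[idx])
        return out


# ---------------------------------------------------------------------------
# DCL mechanics
# ---------------------------------------------------------------------------

def _repulsion_forces(pop: DCLPopulation, U_1: float) -> np.ndarray:
    """Soft-sphere overlap repulsion U_1·(r_i + r_j − d) along centre lines."""
    forces = np.zeros_like(pop.positions)
    if U_1 == 0.0 or pop.n < 2:
        return forces
    rmax = float(pop.radii.max())
    tree = cKDTree(pop.positions)
    pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
    if len(pairs) == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    d = pop.positions[i] - pop.positions[j]
    dist = np.linalg.norm(d, axis=1)
    overlap = pop.radii[i] + pop.radii[j] - dist
    act = overlap > 0
    if not np.any(act):
        return forces
    i, j, d, dist, overlap = i[act], j[act], d[act], dist[act], overlap[act]
    dist = np.maximum(dist, 1e-9)
    f = (U_1 * overlap / dist)[:, None] * d
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def _attraction_forces(positions: np.ndarray, arcs: geom.ArcSet,
                       U_2: float, a_2: float, R: float) -> np.ndarray:
    """Gradient force of the Gaussian border well.

    Potential U(d) = −U_2·ATTRACTION_SCALE·exp(−d²/(2a_2²)) with d the
    geodesic distance to the nearest EVL cell-border arc; the force pulls
    toward the closest border point with magnitude
    U_2·ATTRACTION_SCALE·(d/a_2²)·exp(−d²/(2a_2²)).
    """
    forces = np.zeros_like(positions)
    if U_2 == 0.0:
        return forces
    d, cp = arcs.closest(positions)
    mag = U_2 * ATTRACTION_SCALE * (d / a_2**2) * np.exp(-d**2 / (2 * a_2**2))
    to_border = cp - positions
    n_hat = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    to_border -= np.sum(to_border * n_hat, axis=1, keepdims=True) * n_hat
    norm = np.linalg.norm(to_border, axis=1)
    ok = norm > 1e-9
    forces[ok] = (mag[ok] / norm[ok])[:, None] * to_border[ok]
    return forces


def dcl_step_displacement(pop: DCLPopulation, params: SimParams,
                          arcs: geom.ArcSet,
                          drag_field: _DragField | None,
                          evl_displacement: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """One Euler step of the DCL equation of motion, before re-projection.

    displacement = dt·(F_repulsion + F_attraction) + drag·(Σγ_k Δr_k) + ξ
    with ξ zero-mean Gaussian in the two tangent directions, per-component
    variance 2·D_n·dt.
    """
    dt = params.dt
    disp = dt * _repulsion_forces(pop, params.U_1)
    disp += dt * _attraction_forces(pop.positions, arcs,
                                    params.U_2, params.a_2, params.R)
    if params.drag > 0.0 and drag_field is not None:
        disp += params.drag * drag_field.interpolate(pop.positions,
                                                     evl_displacement)
    if params.sigma > 0.0:
        std = np.sqrt(2.0 * params.D_noise * dt)
        e_t, e_p = geom.tangent_basis(pop.positions)
        xi = rng.normal(0.0, std, (pop.n, 2))
        disp += xi[:, :1] * e_t + xi[:, 1:] * e_p
    return disp


def apply_divisions(pop: DCLPopulation, t: float,
                    rng: np.random.Generator,
                    R: float = geom.EGG_RADIUS_UM) -> DCLPopulation:
    """Execute all divisions due by time t.

    Each due parent is replaced by two daughters of radius (1/2)^(1/3) times
    the parent's, placed ± one parent radius apart along a random tangent
    direction, both flagged as divided.
    """
    due = [ev for ev in pop.division_schedule if ev[0] <= t]
    if not due:
        return pop
    out = pop.copy()
    out.division_schedule = [ev for ev in pop.division_schedule if ev[0] > t]
    next_id = int(out.ids.max()) + 1
    for _, cell_id in due:
        k = np.flatnonzero(out.ids == cell_id)
        if len(k) == 0:
            raise ValueError(f"division scheduled for unknown cell {cell_id}")
        k = int(k[0])
        if out.has_divided[k]:
            raise ValueError(f"cell {cell_id} scheduled to divide twice")
        r = out.radii[k]
        p = out.positions[k]
        e_t, e_p = geom.tangent_basis(p)
        ang = rng.uniform(-np.pi, np.pi)
        u = np.cos(ang) * e_t + np.sin(ang) * e_p
        d1 = geom.radial_project(p + 0.5 * r * u, None, R)
        d2 = geom.radial_project(p - 0.5 * r * u, None, R)
        r_new = r * 0.5 ** (1.0 / 3.0)
        out.positions[k] = d1
        out.radii[k] = r_new
        out.has_divided[k] = True
        out.ids = np.append(out.ids, next_id)
        out.positions = np.vstack([out.positions, d2])
        out.radii = np.append(out.radii, r_new)
        out.has_divided = np.append(out.has_divided, True)
        next_id += 1
    return out


# ---------------------------------------------------------------------------
# Integration loop
# ---------------------------------------------------------------------------

class Simulation:
    """Forward-Euler integrator for the coupled EVL/DCL system."""

    def __init__(self, params: SimParams, mesh: EVLMesh, pop: DCLPopulation):
        mesh.validate()
        self.params = params.replace(R=mesh.R)
        self.state = SimState(time=0.0, mesh=mesh.copy(), pop=pop.copy())
        self.rng = np.random.default_rng(params.seed)
        self._edge_idx = mesh.border_edge_index()
        self._drag_field: _DragField | None = None
        self._arcs: geom.ArcSet | None = None
        self.refresh_frame_geometry()

    def refresh_frame_geometry(self) -> None:
        """Rebuild the per-frame lookup structures.

        The Delaunay triangulation (drag) and the arc set of cell borders
        (attraction) are rebuilt from the current EVL vertex positions once
        per output frame; the EVL moves ≪1 μm per integration step, so the
        within-frame geometry drift is negligible.
        """
        v = self.state.mesh.vertices
        self._arcs = geom.ArcSet(v[self._edge_idx[:, 0]],
                                 v[self._edge_idx[:, 1]], self.params.R)
        if self.params.drag > 0.0:
            self._drag_field = _DragField(v, self.params.R)

    def step(self) -> None:
        p = self.params
        mesh = self.state.mesh
        old_vertices = mesh.vertices.copy()

        # EVL: bulk spring relaxation + constant-speed margin
        forces = evl_spring_forces(mesh, p.U_0)
        bulk = ~mesh.is_border
        new_v = mesh.vertices.copy()
        new_v[bulk] = geom.radial_project(
            mesh.vertices[bulk] + p.dt * forces[bulk], None, p.R)
        mesh.vertices = new_v
        self.state.mesh = advance_border(mesh, p.V_0, p.dt)
        evl_disp = self.state.mesh.vertices - old_vertices

        # DCL
        pop = self.state.pop
        disp = dcl_step_displacement(pop, p, self._arcs,
                                     self._drag_field, evl_disp, self.rng)
        step_len = np.linalg.norm(disp, axis=1)
        if np.any(step_len > 0.1 * p.R):
            k = int(np.argmax(step_len))
            raise RuntimeError(
                f"integration instability: particle {pop.ids[k]} moved "
                f"{step_len[k]:.1f} μm (> 0.1·R) in one step at "
                f"t={self.state.time:.1f} min")
        pop.positions = geom.radial_project(pop.positions + disp, None, p.R)
        self.state.time += p.dt
        self.state.pop = apply_divisions(pop, self.state.time, self.rng, p.R)

    def run(self) -> pd.DataFrame:
        """Integrate and return the tidy track table.

        Columns: frame, id, layer ∈ {EVL_vertex, DCL}, x, y, z, radius
        (NaN for EVL vertices).  EVL cell polygons are the (static) vertex
        cycles of the input mesh.
        """
        p = self.params
        records = [self._snapshot(0)]
        for f in range(1, p.n_frames):
            self.refresh_frame_geometry()
            for _ in range(p.steps_per_frame):
                self.step()
            records.append(self._snapshot(f))
        return pd.concat(records, ignore_index=True)

    def _snapshot(self, frame: int) -> pd.DataFrame:
        mesh, pop = self.state.mesh, self.state.pop
        evl = pd.DataFrame({
            "frame": frame, "id": np.arange(mesh.n_vertices),
            "layer": "EVL_vertex",
            "x": mesh.vertices[:, 0], "y": mesh.vertices[:, 1],
            "z": mesh.vertices[:, 2], "radius": np.nan,
        })
        dcl = pd.DataFrame({
            "frame": frame, "id": pop.ids, "layer": "DCL",
            "x": pop.positions[:, 0], "y": pop.positions[:, 1],
            "z": pop.positions[:, 2], "radius": pop.radii,
        })
        return pd.concat([evl, dcl], ignore_index=True)


def run_simulation(params: SimParams, mesh: EVLMesh,
                   pop: DCLPopulation) -> pd.DataFrame:
    """Run the three-force model; fully reproducible from ``params.seed``."""
    return Simulation(params, mesh, pop).run()
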