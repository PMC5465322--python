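"""Synthetic inputs with known ground truth.

The original observations behind this model are 4D confocal movies that were
never publicly archived, so every pipeline input is emulated here: animal-cap
EVL tessellations, experiment-like track tables produced by the simulator,
pure random walks on the sphere, analytic EVL deformation scenarios, and
voxel label masks for the morphometrics module.  Every generator is a pure
function of (configuration, seed).

Default condition (mirroring the imaged embryos): a 592 μm egg whose animal
cap holds 50–60 polygonal EVL cells, with 100–120 deep cells underneath that
double once by asynchronous division, imaged every 10 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi

from . import geometry as geom
from .mesh import EVLMesh
from .params import SimParams


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic embryo."""

    n_evl_cells: int = 55       # 50-60 in the imaged embryos
    n_dcl_cells: int = 110      # 100-120, doubling once during the run
    R: float = geom.EGG_RADIUS_UM
    cap_extent: float = 1.2     # initial margin polar angle, rad (~30% epiboly)
    V_0: float = 0.25           # margin speed, μm/min
    frame_interval: float = 10.0  # imaging cadence, min
    n_frames: int = 60
    division_window: tuple[float, float] | None = None  # min; default (0.1, 0.9)·T
    dcl_radius: float = 15.0    # deep-cell radius, μm
    seed: int = 0

    def window(self) -> tuple[float, float]:
        if self.division_window is not None:
            return self.division_window
        total = (self.n_frames - 1) * self.frame_interval  # simulated span
        return (0.1 * total, 0.9 * total)


# ---------------------------------------------------------------------------
# EVL cap tessellation
# ---------------------------------------------------------------------------

def _bounded_voronoi(points: np.ndarray, disc: shapely.Polygon,
                     rho_max: float) -> list[shapely.Polygon]:
    """Voronoi cells of `points` clipped to the disc.

    Generators are mirrored across the disc boundary so every interior cell
    is finite; each cell is then intersected with the (convex, polygonal)
    disc, which keeps cells convex and lets adjacent cells share boundary
    vertices exactly.
    """
    r = np.linalg.norm(points, axis=1)
    r = np.where(r < 1e-9, 1e-9, r)
    mirrored = points * ((2.0 * rho_max - r) / r)[:, None]
    vor = Voronoi(np.vstack([points, mirrored]))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi cell despite mirroring")
        poly = shapely.Polygon(vor.vertices[region])
        clipped = poly.intersection(disc)
        if clipped.is_empty or clipped.geom_type != "Polygon":
            raise RuntimeError("degenerate clipped Voronoi cell")
        cells.append(shapely.geometry.polygon.orient(clipped, sign=1.0))
    return cells


def make_evl_tessellation(n_cells: int = 55, R: float = geom.EGG_RADIUS_UM,
                          cap_extent: float = 1.2, seed: int = 0,
                          lloyd_iters: int = 40) -> EVLMesh:
    """Lloyd-relaxed Voronoi tessellation of the animal cap.

    The cap (polar angle ≤ ``cap_extent``) is mapped to a disc by the
    azimuthal equidistant projection, tessellated there by centroidal
    (Lloyd-relaxed) Voronoi cells, and the polygon vertices lifted back to
    the sphere.  Cells come out convex, simple and closed, sharing vertices
    with their neighbours; vertices on the disc boundary are flagged as the
    free epibolic margin.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 EVL cells")
    rng = np.random.default_rng(seed)
    rho_max = R * cap_extent
    # boundary chords ~16 μm: fine enough that the polygonal margin carries
    # the full cap area to ~1e-4 relative
    n_arc = max(64, int(np.ceil(2 * np.pi * rho_max / 16.0)))
    disc = shapely.Point(0.0, 0.0).buffer(rho_max, quad_segs=n_arc // 4)
    if 2 * np.pi * rho_max / n_cells < 1.0:
        raise ValueError("cap too small for the requested cell count")

    # seeds uniform on the cap (uniform in cos θ), expressed in projection
    cos_t = rng.uniform(np.cos(cap_extent), 1.0, n_cells)
    theta = np.arccos(cos_t)
    phi = rng.uniform(-np.pi, np.pi, n_cells)
    pts = np.column_stack([R * theta * np.cos(phi), R * theta * np.sin(phi)])

    for _ in range(lloyd_iters):
        cells2d = _bounded_voronoi(pts, disc, rho_max)
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells2d])
    cells2d = _bounded_voronoi(pts, disc, rho_max)

    # shared-vertex indexing (coordinates keyed to nm precision)
    vert_index: dict[tuple[int, int], int] = {}
    verts2d: list[tuple[float, float]] = []
    cycles: list[list[int]] = []
    for poly in cells2d:
        cyc = []
        for x, y in list(poly.exterior.coords)[:-1]:
            key = (round(x * 1e3), round(y * 1e3))
            if key not in vert_index:
                vert_index[key] = len(verts2d)
                verts2d.append((x, y))
            idx = vert_index[key]
            if not cyc or cyc[-1] != idx:
                cyc.append(idx)
        if cyc[0] == cyc[-1]:
            cyc.pop()
        cycles.append(cyc)

    v2 = np.array(verts2d)
    rho = np.linalg.norm(v2, axis=1)
    is_border = rho >= rho_max * (1.0 - 1e-6)
    # snap margin vertices onto the exact margin circle
    v2[is_border] *= (rho_max / rho[is_border])[:, None]
    verts3d = geom.azimuthal_equidistant_inverse(v2, R)
    m = EVLMesh(vertices=verts3d, cells=cycles, is_border=is_border, R=R)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# DCL placement, divisions, reference dataset
# ---------------------------------------------------------------------------

def place_dcl_uniform(n: int, R: float, cap_extent: float,
                      rng: np.random.Generator,
                      margin_pad: float = 0.03) -> np.ndarray:
    """Uniform positions over the cap, padded slightly inside the margin."""
    theta_max = cap_extent * (1.0 - margin_pad)
    cos_t = rng.uniform(np.cos(theta_max), 1.0, n)
    theta = np.arccos(cos_t)
    phi = rng.uniform(-np.pi, np.pi, n)
    return geom.from_spherical(theta, phi, R)


def make_division_schedule(ids: np.ndarray, window: tuple[float, float],
                           rng: np.random.Generator) -> list[tuple[float, int]]:
    """One asynchronous division per cell, uniform over the window."""
    times = rng.uniform(window[0], window[1], len(ids))
    return sorted(zip(times.tolist(), ids.tolist()))


def initial_conditions(cfg: SyntheticConfig):
    """Deterministic initial (mesh, population) for a configuration.

    The same config and seed always rebuild the identical starting state,
    which is how simulated and reference datasets share cell identities
    ("matching by construction") during parameter fitting.
    """
    from .simulate import DCLPopulation

    rng = np.random.default_rng(cfg.seed)
    mesh = make_evl_tessellation(cfg.n_evl_cells, cfg.R, cfg.cap_extent,
                                 seed=cfg.seed)
    pos = place_dcl_uniform(cfg.n_dcl_cells, cfg.R, cfg.cap_extent, rng)
    ids = np.arange(cfg.n_dcl_cells)
    pop = DCLPopulation(
        ids=ids, positions=pos,
        radii=np.full(cfg.n_dcl_cells, cfg.dcl_radius),
        has_divided=np.zeros(cfg.n_dcl_cells, bool),
        division_schedule=make_division_schedule(ids, cfg.window(), rng))
    return mesh, pop


def make_reference_dataset(cfg: SyntheticConfig | None = None,
                           params: SimParams | None = None):
    """Experiment-like track table with a sealed ground-truth record.

    Builds a tessellated cap and a uniformly seeded DCL population, runs the
    three-force simulator, and returns ``(tracks, cells, truth)`` where
    ``truth`` records the generating parameters for recovery tests.
    """
    from .simulate import run_simulation

    cfg = cfg or SyntheticConfig()
    params = params or SimParams()
    params = params.replace(R=cfg.R, V_0=cfg.V_0, n_frames=cfg.n_frames,
                            frame_interval=cfg.frame_interval, seed=cfg.seed)
    mesh, pop = initial_conditions(cfg)
    tracks = run_simulation(params, mesh, pop)
    truth = {"params": params.to_dict(), "config": cfg.__dict__.copy()}
    return tracks, mesh.cells, truth


# ---------------------------------------------------------------------------
# Random walks
# ---------------------------------------------------------------------------

def make_random_walks(n: int, D_auto: float, dt: float, n_frames: int,
                      R: float = geom.EGG_RADIUS_UM, seed: int = 0,
                      start_theta: float = 0.5):
    """Independent tangential Brownian tracks on the sphere.

    Per-step displacement is Gaussian in the local tangent plane with
    per-component variance 2·D_auto·dt, then re-projected radially; for
    steps small against R this realises a surface random walk with
    MSD(τ) = 4·D_auto·τ.

    Returns a tidy DataFrame (frame, id, layer, x, y, z).
    """
    import pandas as pd

    if D_auto < 0:
        raise ValueError("D_auto must be nonnegative")
    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(np.cos(start_theta), 1.0, n)
    pos = geom.from_spherical(np.arccos(cos_t),
                              rng.uniform(-np.pi, np.pi, n), R)
    std = np.sqrt(2.0 * D_auto * dt)
    rows = []
    for f in range(n_frames):
        rows.append(pos.copy())
        if f == n_frames - 1:
            break
        e_t, e_p = geom.tangent_basis(pos)
        xi = rng.normal(0.0, std, (n, 2))
        pos = geom.radial_project(pos + xi[:, :1] * e_t + xi[:, 1:] * e_p,
                                  None, R)
    out = pd.DataFrame({
        "frame": np.repeat(np.arange(n_frames), n),
        "id": np.tile(np.arange(n), n_frames),
        "layer": "DCL",
        "x": np.concatenate([r[:, 0] for r in rows]),
        "y": np.concatenate([r[:, 1] for r in rows]),
        "z": np.concatenate([r[:, 2] for r in rows]),
    })
    return out


# ---------------------------------------------------------------------------
# Deformation scenarios for the decomposition module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationScenario:
    """EVL vertex tracks deformed by a known analytic field."""
    frame0: np.ndarray           # (n_v, 3)
    frame1: np.ndarray           # (n_v, 3)
    field: object                # callable points -> true displacements
    cells: list                  # EVL cell vertex cycles


def make_deformation_scenario(variant: str, magnitude: float,
                              n_cells: int = 30,
                              R: float = geom.EGG_RADIUS_UM,
                              cap_extent: float = 1.0, seed: int = 0
                              ) -> DeformationScenario:
    """Analytic EVL deformation with the exact field returned.

    ``isotropic``: every vertex's polar arc from the pole scales by
    (1 + magnitude); ``anisotropic``: in the azimuthal equidistant
    projection, x scales by (1 + magnitude) and y by (1 + magnitude/2) —
    a direction-dependent stretch of the cap.  Vertices come from a cap
    tessellation so all three deformation models (including the
    cell-centre-of-mass one) can be evaluated against the field.
    """
    if variant not in ("isotropic", "anisotropic"):
        raise ValueError(f"unknown scenario {variant!r}")
    m = make_evl_tessellation(n_cells, R, cap_extent, seed=seed)
    frame0 = m.vertices

    if variant == "isotropic":
        def field(pts: np.ndarray) -> np.ndarray:
            theta, phi = geom.spherical_coords(pts)
            return geom.from_spherical(theta * (1.0 + magnitude), phi, R) - pts
    else:
        sx, sy = 1.0 + magnitude, 1.0 + 0.5 * magnitude

        def field(pts: np.ndarray) -> np.ndarray:
            xy = geom.azimuthal_equidistant(pts, R)
            new = geom.azimuthal_equidistant_inverse(
                np.stack([xy[..., 0] * sx, xy[..., 1] * sy], axis=-1), R)
            return new - pts

    frame1 = frame0 + field(frame0)
    return DeformationScenario(frame0=frame0, frame1=frame1, field=field,
                               cells=m.cells)


# ---------------------------------------------------------------------------
# Label-mask fixtures for morphometrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtrusionSpec:
    """A synthetic protrusion attached to the cell body.

    kind 'bar' is a thin rectangle (elongated protrusion ground truth);
    'bump' is a half-disc (round protrusion ground truth).  ``angle`` is the
    direction from the body centre, radians; sizes are in pixels.
    """
    kind: str  # 'bar' | 'bump'
    angle: float
    length: float = 30.0   # px; at 0.22 μm/px a 30×2 bar is ≈2.9 μm²
    width: float = 2.0
    radius: float = 6.0    # px; bump half-disc ≈ 2.7 μm² at 0.22 μm/px


def make_label_masks(body_radius: float = 14.0,
                     protrusions: tuple[ProtrusionSpec, ...] = (),
                     shape: tuple[int, int] = (110, 110),
                     spacing: tuple[float, float] = (0.22, 0.22)):
    """Synthetic 2D body/membrane mask pair (body ⊂ membrane).

    The membrane mask is the body plus the requested protrusion shapes, as
    produced by a membrane segmentation that includes protrusive structures;
    the body mask is the smooth cell body alone.  Returns
    ``(body, membrane, spacing)`` with uint8 masks.
    """
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    body = ((yy - cy) ** 2 + (xx - cx) ** 2) <= body_radius**2
    membrane = body.copy()
    for p in protrusions:
        dy, dx = np.sin(p.angle), np.cos(p.angle)
        if p.kind == "bar":
            # axis-aligned distance to the bar's centre line
            t = (xx - cx) * dx + (yy - cy) * dy      # along protrusion axis
            s = -(xx - cx) * dy + (yy - cy) * dx     # across
            bar = (t >= body_radius - 1.5) & (t <= body_radius + p.length) \
                & (np.abs(s) <= p.width / 2.0)
            membrane |= bar
        elif p.kind == "bump":
            by = cy + dy * (body_radius + 0.0)
            bx = cx + dx * (body_radius + 0.0)
            bump = ((yy - by) ** 2 + (xx - bx) ** 2) <= p.radius**2
            membrane |= bump
        else:
            raise ValueError(f"unknown protrusion kind {p.kind!r}")
    if not protrusions:
        pass
    elif not np.any(membrane & ~body):
        raise ValueError("protrusion does not extend beyond the body")
    return body.astype(np.uint8), membrane.astype(np.uint8), spacing
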