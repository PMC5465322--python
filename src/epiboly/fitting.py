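"""Target functions and simplex fitting of the model to track statistics.

The free parameters of the three-force model are fitted by comparing
summary statistics between a simulation and a reference dataset:

* EVL: squared differences of corresponding EVL cell areas (fits ``U_0``);
* DCL: a weighted sum of L2 discrepancies between four statistics — the
  mean distance to the six nearest DCL neighbours per frame, the
  probability density of the distance to the nearest EVL cell border, the
  mean square displacement curve, and the probability density of the
  per-frame displacement (fits ``sigma``, ``U_1``, ``U_2`` and ``drag``).

Optimisation is Nelder–Mead simplex descent with optional restarts; global
structure is examined by brute-force sampling of the parameter landscape.
Simulation stochasticity inside the objective is handled with common random
numbers (a fixed per-evaluation seed), so the objective is deterministic
for the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize

from . import metrics as mtr
from . import tracks as trk
from .mesh import EVLMesh
from .params import SimParams
from .simulate import DCLPopulation, run_simulation

DEFAULT_STATS = ("nn6_distance", "border_distance_pdf", "msd",
                 "step_displacement_pdf")


@dataclass(frozen=True)
class TargetSpec:
    """Which DCL statistics enter the target and how they are binned."""
    statistics: tuple[str, ...] = DEFAULT_STATS
    weights: tuple[float, ...] | None = None   # default: equal
    border_bin_width: float = 5.0              # μm
    border_R_c: float = 120.0                  # μm
    step_bins: int = 20
    step_max: float = 40.0                     # μm per frame
    max_lag: int = 25
    frame_stride: int = 2                      # frames sampled for border pdf

    def __post_init__(self) -> None:
        if not self.statistics:
            raise ValueError("need at least one statistic")
        if self.weights is not None:
            if len(self.weights) != len(self.statistics):
                raise ValueError("one weight per statistic")
            if any(w < 0 for w in self.weights):
                raise ValueError("weights must be nonnegative")


# ---------------------------------------------------------------------------
# EVL target
# ---------------------------------------------------------------------------

def target_evl(sim_areas: pd.DataFrame, ref_areas: pd.DataFrame) -> float:
    """Sum of squared, scale-normalised EVL cell-area differences.

    Both inputs have columns (frame, cell_id, area) with matching cell
    identities; the normalisation scale is the mean reference area.
    """
    key = ["frame", "cell_id"]
    sim = sim_areas.set_index(key)["area"]
    ref = ref_areas.set_index(key)["area"]
    missing = ref.index.difference(sim.index)
    if len(missing):
        raise ValueError(f"unmatched EVL cells/frames: {list(missing)[:10]}")
    scale = float(ref.mean())
    diff = (sim.loc[ref.index].to_numpy() - ref.to_numpy()) / scale
    return float(np.sum(diff**2))


def evl_cell_areas(tracks: pd.DataFrame, cells: list[list[int]]
                   ) -> pd.DataFrame:
    """Per-frame spherical areas of every EVL cell in a track table."""
    from . import geometry as geom

    rows = []
    for f in np.sort(tracks.loc[tracks.layer == "EVL_vertex",
                                "frame"].unique()):
        v = trk.positions(tracks, frame=int(f), layer="EVL_vertex")
        R = float(np.linalg.norm(v, axis=1).mean())
        for c, cyc in enumerate(cells):
            rows.append((int(f), c,
                         geom.spherical_polygon_area(v[list(cyc)], R)))
    return pd.DataFrame(rows, columns=["frame", "cell_id", "area"])


# ---------------------------------------------------------------------------
# DCL statistics and target
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DCLStatistics:
    """The four summary curves the DCL target compares."""
    nn6_distance: np.ndarray           # per sampled frame, μm
    border_distance_pdf: np.ndarray    # density on fixed bins, 1/μm
    msd: np.ndarray                    # per lag, μm²
    step_displacement_pdf: np.ndarray  # density on fixed bins, 1/μm

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "nn6_distance": self.nn6_distance,
            "border_distance_pdf": self.border_distance_pdf,
            "msd": self.msd,
            "step_displacement_pdf": self.step_displacement_pdf,
        }


def compute_dcl_statistics(tracks: pd.DataFrame, cells: list[list[int]],
                           spec: TargetSpec = TargetSpec(),
                           R: float | None = None) -> DCLStatistics:
    """Measure the four DCL summary statistics of a track table."""
    from . import geometry as geom

    dcl = tracks[tracks.layer == "DCL"]
    frames = np.sort(dcl["frame"].unique())
    if R is None:
        v = trk.positions(tracks, frame=int(frames[0]), layer="EVL_vertex")
        R = float(np.linalg.norm(v, axis=1).mean())

    nn6 = np.array([
        mtr.nearest_neighbour_distance(
            trk.positions(dcl, frame=int(f)), k=6, R=R).mean()
        for f in frames])

    dists = []
    for f in frames[::spec.frame_stride]:
        a, b = mtr.evl_border_arcs(tracks, cells, int(f))
        pos = trk.positions(dcl, frame=int(f))
        dists.append(geom.ArcSet(a, b, R).min_distance(pos))
    border = mtr.distance_to_border_distribution(
        np.concatenate(dists), bin_width=spec.border_bin_width,
        R_c=spec.border_R_c).density

    _, arr = trk.track_matrix(tracks, "DCL")
    msd_curve = mtr.msd(arr, max_lag=spec.max_lag).msd

    steps = np.linalg.norm(np.diff(arr, axis=0), axis=2).ravel()
    edges = np.linspace(0.0, spec.step_max, spec.step_bins + 1)
    step_pdf, _ = np.histogram(steps, bins=edges, density=True)

    return DCLStatistics(nn6_distance=nn6, border_distance_pdf=border,
                         msd=msd_curve, step_displacement_pdf=step_pdf)


def target_dcl(sim_stats: DCLStatistics, ref_stats: DCLStatistics,
               spec: TargetSpec = TargetSpec(),
               return_components: bool = False):
    """Weighted sum of symmetric, scale-normalised L2 discrepancies.

    Each statistic contributes ‖s − r‖² / scale² with
    scale = (‖s‖ + ‖r‖)/2, making the metric symmetric in its arguments
    and dimensionless across statistics of different units.  Statistics
    that are empty on either side are excluded with a warning.
    """
    import logging
    log = logging.getLogger(__name__)

    sims = sim_stats.as_dict()
    refs = ref_stats.as_dict()
    weights = spec.weights or tuple(1.0 for _ in spec.statistics)
    total = 0.0
    components: dict[str, float] = {}
    for name, w in zip(spec.statistics, weights):
        s, r = sims[name], refs[name]
        if s.size == 0 or r.size == 0 or s.size != r.size:
            log.warning("statistic %s empty or mismatched; excluded", name)
            continue
        scale = 0.5 * (np.linalg.norm(s) + np.linalg.norm(r))
        comp = float(np.sum((s - r) ** 2) / scale**2) if scale > 0 else 0.0
        components[name] = comp
        total += w * comp
    if return_components:
        return total, components
    return total


# ---------------------------------------------------------------------------
# Simplex optimisation
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a simplex fit."""
    names: tuple[str, ...]
    x_opt: np.ndarray
    fun: float
    trace: list[tuple[np.ndarray, float]] = field(default_factory=list)
    nfev: int = 0
    seed: int | None = None

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.x_opt)))


def optimize(objective, x0, bounds=None, names: tuple[str, ...] | None = None,
             restarts: int = 0, seed: int = 0, xatol: float = 1e-3,
             fatol: float = 1e-4, max_evals: int = 200) -> FitResult:
    """Nelder–Mead descent of a (possibly simulation-backed) objective.

    With ``restarts`` > 0 additional starts are drawn uniformly within
    ``bounds`` and the best end point kept.  Every evaluation is recorded
    in the trace; non-finite objective values abort with the offending
    parameter vector in the message.
    """
    x0 = np.asarray(x0, float)
    names = names or tuple(f"x{i}" for i in range(len(x0)))
    trace: list[tuple[np.ndarray, float]] = []

    def wrapped(x):
        f = objective(np.asarray(x, float))
        if not np.isfinite(f):
            raise RuntimeError(f"non-finite objective at {x}")
        trace.append((np.array(x, float), float(f)))
        return f

    rng = np.random.default_rng(seed)
    starts = [x0]
    if restarts > 0:
        if bounds is None:
            raise ValueError("restarts need bounds to sample from")
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts += [rng.uniform(lo, hi) for _ in range(restarts)]
    best = None
    for s in starts:
        res = sp_optimize.minimize(
            wrapped, s, method="Nelder-Mead", bounds=bounds,
            options={"xatol": xatol, "fatol": fatol, "maxfev": max_evals,
                     "adaptive": True})
        if best is None or res.fun < best.fun:
            best = res
    # guarantee the contract final <= initial even if descent stalled
    f0 = wrapped(x0) if not trace else trace[0][1]
    if best.fun > f0:
        x_opt, fun = x0, f0
    else:
        x_opt, fun = np.asarray(best.x, float), float(best.fun)
    return FitResult(names=names, x_opt=x_opt, fun=fun, trace=trace,
                     nfev=len(trace), seed=seed)


def sample_landscape(grid: dict[str, np.ndarray], objective
                     ) -> pd.DataFrame:
    """Brute-force normalised objective over a parameter grid.

    Returns a tidy frame with one row per grid point, the raw objective and
    its min–max normalisation to [0, 1]; the row order preserves the grid
    product order and the minimum's location is where ``normalized == 0``.
    """
    names = list(grid)
    meshes = np.meshgrid(*[np.asarray(grid[n], float) for n in names],
                         indexing="ij")
    points = np.column_stack([m.ravel() for m in meshes])
    vals = np.array([objective(p) for p in points])
    lo, hi = vals.min(), vals.max()
    norm = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo)
    out = pd.DataFrame(points, columns=names)
    out["target"] = vals
    out["normalized"] = norm
    return out


# ---------------------------------------------------------------------------
# Simulation-backed objective
# ---------------------------------------------------------------------------

def make_simulation_objective(ref_tracks: pd.DataFrame,
                              ref_cells: list[list[int]],
                              mesh: EVLMesh, pop: DCLPopulation,
                              base_params: SimParams,
                              free: tuple[str, ...],
                              spec: TargetSpec = TargetSpec(),
                              eval_seed: int = 12345):
    """Objective θ ↦ target_dcl(sim(θ), reference).

    The reference statistics are measured once; each evaluation re-runs the
    simulator from the same initial mesh/population with the candidate
    parameters and a fixed seed (common random numbers).
    """
    ref_stats = compute_dcl_statistics(ref_tracks, ref_cells, spec)

    def objective(theta: np.ndarray) -> float:
        params = base_params.replace(seed=eval_seed,
                                     **dict(zip(free, map(float, theta))))
        sim_tracks = run_simulation(params, mesh, pop)
        sim_stats = compute_dcl_statistics(sim_tracks, ref_cells, spec)
        return target_dcl(sim_stats, ref_stats, spec)

    return objective
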