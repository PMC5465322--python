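"""Trajectory and population analytics for track tables.

Implements the cell-parameter measurements used to characterise deep-cell
spreading: greedy distance-based track linking with quality-control flags,
mean-square displacement and random-walk diffusion fitting, directionality,
geodesic nearest-neighbour distances, the distance-to-EVL-border
distribution with its analytic uniform baseline, the convex-hull covered
area, the epiboly index, and the EVL-area/DCL-area regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

from . import geometry as geom
from . import tracks as trk

log = logging.getLogger(__name__)

SPEED_FLAG_UM_PER_FRAME = 35.0
AREA_CHANGE_FLAG = {"EVL_cell": 2.0, "DCL": 0.5}  # relative change per frame


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_tracks(detections: list[pd.DataFrame], layer: str = "DCL"
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy nearest-centroid linking with quality-control flags.

    Each active track is linked to the closest unclaimed detection in the
    next frame, taking candidate pairs in order of increasing distance.
    Links are never dropped silently; instead flags are raised for
    suspicious events: per-frame displacement above 35 μm, relative area
    change above 200% (EVL) or 50% (DCL), track appearance after frame 0,
    and disappearance.

    Parameters
    ----------
    detections : list of DataFrame
        Per-frame detections with columns x, y, z and optionally area.
    layer : str
        'DCL' or 'EVL_cell'; selects the area-change threshold.

    Returns
    -------
    tracks : DataFrame
        Tidy track table (frame, id, layer, x, y, z[, area]).
    flags : DataFrame
        Columns (frame, id, flag, value).
    """
    area_thresh = AREA_CHANGE_FLAG.get(layer)
    rows, flags = [], []
    active: dict[int, dict] = {}
    next_id = 0
    for f, det in enumerate(detections):
        det = det.reset_index(drop=True)
        if len(det) == 0:
            for tid in list(active):
                flags.append((f, tid, "disappear", np.nan))
                del active[tid]
            continue
        pos = det[["x", "y", "z"]].to_numpy()
        claimed = np.zeros(len(det), bool)
        if active:
            tids = list(active)
            last = np.array([active[t]["pos"] for t in tids])
            dist = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            linked_tracks = set()
            for ti, di in order:
                tid = tids[ti]
                if tid in linked_tracks or claimed[di]:
                    continue
                linked_tracks.add(tid)
                claimed[di] = True
                d = dist[ti, di]
                if d > SPEED_FLAG_UM_PER_FRAME:
                    flags.append((f, tid, "speed", d))
                if area_thresh is not None and "area" in det.columns:
                    a_old = active[tid].get("area")
                    a_new = det.loc[di, "area"]
                    if a_old and np.isfinite(a_new) and a_old > 0:
                        rel = abs(a_new - a_old) / a_old
                        if rel > area_thresh:
                            flags.append((f, tid, "area_change", rel))
                active[tid]["pos"] = pos[di]
                active[tid]["area"] = det.loc[di, "area"] \
                    if "area" in det.columns else None
                rows.append((f, tid, *pos[di],
                             det.loc[di, "area"] if "area" in det.columns
                             else np.nan))
            for tid in set(tids) - linked_tracks:
                flags.append((f, tid, "disappear", np.nan))
                del active[tid]
        for di in np.flatnonzero(~claimed):
            tid = next_id
            next_id += 1
            if f > 0:
                flags.append((f, tid, "appear", np.nan))
            active[tid] = {"pos": pos[di],
                           "area": det.loc[di, "area"]
                           if "area" in det.columns else None}
            rows.append((f, tid, *pos[di],
                         det.loc[di, "area"] if "area" in det.columns
                         else np.nan))
    out = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "z", "area"])
    out.insert(2, "layer", layer)
    return out, pd.DataFrame(flags, columns=["frame", "id", "flag", "value"])


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSDCurve:
    """Mean squared 3D displacement per time lag (frames)."""
    lags: np.ndarray     # 1..max_lag, frames
    msd: np.ndarray      # μm²
    counts: np.ndarray   # windows contributing per lag


def msd(track_positions, max_lag: int = 25, per_track: bool = False
        ) -> MSDCurve:
    """Sliding-window MSD over all tracks.

    For every lag τ = 1..max_lag the squared 3D Euclidean displacement
    between window start and end is averaged over all sliding windows of
    all tracks (pooled, the default) or first per track and then across
    tracks (``per_track``).

    ``track_positions`` is a (n_frames, n_tracks, 3) array or a track-table
    DataFrame (its DCL layer is used).
    """
    if isinstance(track_positions, pd.DataFrame):
        _, arr = trk.track_matrix(track_positions, "DCL")
    else:
        arr = np.asarray(track_positions, float)
        if arr.ndim == 2:
            arr = arr[:, None, :]
    n_frames = arr.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames for an MSD")
    if max_lag >= n_frames:
        log.warning("max_lag %d >= track length %d; truncating",
                    max_lag, n_frames)
        max_lag = n_frames - 1
    lags = np.arange(1, max_lag + 1)
    vals = np.empty(max_lag)
    counts = np.empty(max_lag, int)
    for i, lag in enumerate(lags):
        sq = np.sum((arr[lag:] - arr[:-lag]) ** 2, axis=2)  # (windows, tracks)
        counts[i] = sq.size
        vals[i] = sq.mean(axis=0).mean() if per_track else sq.mean()
    return MSDCurve(lags=lags, msd=vals, counts=counts)


@dataclass(frozen=True)
class DiffusionFit:
    """Linear random-walk fit of an MSD curve."""
    D_auto: float       # μm² per time unit of `dt`
    r_squared: float
    slope: float
    intercept: float


def fit_diffusion(curve: MSDCurve, dt: float = 1.0) -> DiffusionFit:
    """OLS fit MSD = slope·τ + intercept; D = slope/4.

    The slope/4 convention is the 2-D surface random walk: motion is
    confined to the (locally flat) sphere surface, so two tangential
    degrees of freedom contribute.  ``dt`` is the frame interval in the
    time unit D should be reported in.
    """
    if len(curve.lags) < 3:
        raise ValueError("need at least 3 lags to fit a diffusion law")
    if np.all(curve.msd == 0):
        log.warning("all-zero MSD: D = 0, r² undefined")
        return DiffusionFit(D_auto=0.0, r_squared=np.nan, slope=0.0,
                            intercept=0.0)
    res = stats.linregress(curve.lags * dt, curve.msd)
    return DiffusionFit(D_auto=res.slope / 4.0, r_squared=res.rvalue**2,
                        slope=res.slope, intercept=res.intercept)


def directionality(track: np.ndarray) -> float:
    """Net displacement over path length, both 3D; 1 = straight line."""
    p = np.asarray(track, float)
    if len(p) < 2:
        raise ValueError("need at least 2 frames")
    path = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
    if path == 0:
        log.warning("zero path length: directionality undefined")
        return np.nan
    return float(np.linalg.norm(p[-1] - p[0]) / path)


# ---------------------------------------------------------------------------
# Spatial statistics
# ---------------------------------------------------------------------------

def nearest_neighbour_distance(positions: np.ndarray, k: int,
                               R: float = geom.EGG_RADIUS_UM) -> np.ndarray:
    """Per-cell mean geodesic distance to its k nearest neighbours.

    Both k=3 (distance-matrix average of the three closest) and k=6 (the
    six-nearest-neighbour dispersion measure) are used downstream.
    """
    pos = np.asarray(positions, float)
    n = len(pos)
    if k >= n:
        raise ValueError(f"k={k} requires more than k points (got {n})")
    u = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    ang = np.arccos(np.clip(u @ u.T, -1.0, 1.0))
    d = R * ang
    np.fill_diagonal(d, np.inf)
    part = np.partition(d, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


@dataclass(frozen=True)
class BorderDistanceDistribution:
    """Histogram of DCL distance to the nearest EVL cell border."""
    bin_edges: np.ndarray    # μm
    density: np.ndarray      # probability density, 1/μm
    counts: np.ndarray
    R_c: float               # equivalent EVL cell surface radius, μm

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def modal_distance(self) -> float:
        """Centre of the modal bin, μm."""
        return float(self.midpoints[np.argmax(self.counts)])

    def baseline(self, d: np.ndarray | None = None) -> np.ndarray:
        """Analytic density for uniform points in a disc of radius R_c.

        For a point uniform in a disc of radius R_c around the cell centre,
        the distance to the rim has density p(d) = 2(R_c − d)/R_c², the
        straight-line random reference drawn in the experimental
        distributions.
        """
        x = self.midpoints if d is None else np.asarray(d, float)
        return np.clip(2.0 * (self.R_c - x) / self.R_c**2, 0.0, None)


def border_distances(dcl_positions: np.ndarray, arc_a: np.ndarray,
                     arc_b: np.ndarray,
                     R: float = geom.EGG_RADIUS_UM) -> np.ndarray:
    """Geodesic distance of each DCL position to the nearest border arc."""
    return geom.ArcSet(arc_a, arc_b, R).min_distance(
        np.atleast_2d(dcl_positions))


def distance_to_border_distribution(distances: np.ndarray,
                                    bin_width: float = 5.0,
                                    R_c: float = 120.0
                                    ) -> BorderDistanceDistribution:
    """Normalised histogram of border distances plus the uniform baseline.

    ``distances`` may come from :func:`border_distances` (simulation /
    tracked data) or any other source; values beyond R_c land in the last
    bin's tail and are excluded from the density support.
    """
    d = np.asarray(distances, float)
    edges = np.arange(0.0, R_c + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no distances within [0, R_c]")
    density = counts / (total * bin_width)
    return BorderDistanceDistribution(bin_edges=edges, density=density,
                                      counts=counts, R_c=R_c)


def evl_border_arcs(tracks: pd.DataFrame, cells: list[list[int]],
                    frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-border arc endpoints for one frame of a track table."""
    v = trk.positions(tracks, frame=frame, layer="EVL_vertex")
    seen = set()
    for cyc in cells:
        for k in range(len(cyc)):
            i, j = cyc[k], cyc[(k + 1) % len(cyc)]
            seen.add((min(i, j), max(i, j)))
    idx = np.array(sorted(seen), int)
    return v[idx[:, 0]], v[idx[:, 1]]


def covered_area(dcl_positions: np.ndarray,
                 R: float = geom.EGG_RADIUS_UM) -> float:
    """Spherical area of the DCL convex hull.

    The hull is taken over the 2D (x, y) projection of the cell centres,
    ignoring z; its vertex cells are lifted back to the sphere and the
    spherical polygon area returned.
    """
    pos = np.asarray(dcl_positions, float)
    if len(pos) < 3:
        raise ValueError("need at least 3 cells for a covered area")
    hull = ConvexHull(pos[:, :2])  # raises QhullError for collinear input
    return geom.spherical_polygon_area(pos[hull.vertices], R)


def epiboly_index(margin_positions: np.ndarray,
                  R: float = geom.EGG_RADIUS_UM) -> float:
    """Percent progression of the blastoderm margin along the AV axis.

    Defined as 100·(R − z̄)/(2R) with z̄ the mean margin height: 0% at the
    animal pole, 50% at the equator, 100% at the vegetal pole.
    """
    pos = np.atleast_2d(np.asarray(margin_positions, float))
    if pos.size == 0:
        raise ValueError("empty margin")
    return float(100.0 * (R - pos[:, 2].mean()) / (2.0 * R))


@dataclass(frozen=True)
class AreaRelation:
    slope: float
    intercept: float
    r_squared: float


def area_relation(evl_areas: np.ndarray, dcl_areas: np.ndarray
                  ) -> AreaRelation:
    """OLS regression of DCL covered area on total EVL area across frames."""
    x = np.asarray(evl_areas, float)
    y = np.asarray(dcl_areas, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of >= 3 frames")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant series: r² undefined")
        return AreaRelation(slope=np.nan, intercept=np.nan, r_squared=np.nan)
    res = stats.linregress(x, y)
    return AreaRelation(slope=res.slope, intercept=res.intercept,
                        r_squared=res.rvalue**2)
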