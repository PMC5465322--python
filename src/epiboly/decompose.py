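"""Decomposition of deep-cell trajectories into advected and autonomous parts.

A deep cell adhering to the expanding EVL moves partly because the substrate
underneath it deforms (non-autonomous advection) and partly by its own
motility (autonomous).  The advected component is estimated from the EVL
vertex trajectories through a geometric deformation model and subtracted per
frame pair; three models are compared:

``two_closest_vertices``
    displacement of the two nearest EVL vertices (inverse-distance-weighted
    mean by default, plain mean optionally);
``cell_center_of_mass``
    displacement of the vertex centroid of the EVL cell containing the
    point;
``delaunay_barycentric``
    barycentric interpolation over the enclosing triangle of the EVL-vertex
    Delaunay triangulation in the 2D animal-pole projection, with the
    weights γ recomputed at each frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from . import geometry as geom

log = logging.getLogger(__name__)

MODELS = ("two_closest_vertices", "cell_center_of_mass",
          "delaunay_barycentric")


@dataclass(frozen=True)
class DecomposedTrack:
    """Per-frame displacement split: total = advected + autonomous, exactly."""
    total: np.ndarray         # (n_frames-1, 3) μm
    advected: np.ndarray      # (n_frames-1, 3)
    autonomous: np.ndarray    # (n_frames-1, 3)
    positions: np.ndarray     # (n_frames, 3) original track
    flags: np.ndarray         # (n_frames-1,) True where a fallback was used

    @property
    def autonomous_track(self) -> np.ndarray:
        """Cumulative autonomous trajectory (starts at the track origin)."""
        return np.vstack([self.positions[0],
                          self.positions[0] + np.cumsum(self.autonomous,
                                                        axis=0)])


def _point_in_cell(xy: np.ndarray, poly: np.ndarray) -> bool:
    """Even-odd point-in-polygon in the 2D projection."""
    x, y = xy
    px, py = poly[:, 0], poly[:, 1]
    j = np.roll(np.arange(len(poly)), 1)
    cond = ((py > y) != (py[j] > y)) & (
        x < (px[j] - px) * (y - py) / np.where(py[j] == py, np.inf, py[j] - py)
        + px)
    return bool(np.count_nonzero(cond) % 2)


def advected_displacement(p: np.ndarray, evl_t0: np.ndarray,
                          evl_t1: np.ndarray, model: str,
                          cells: list[list[int]] | None = None,
                          R: float = geom.EGG_RADIUS_UM,
                          inverse_distance: bool = True
                          ) -> tuple[np.ndarray, bool]:
    """Predicted substrate displacement at point p over one frame pair.

    Returns ``(displacement, fallback)`` where ``fallback`` marks points
    outside the triangulation/cells that were handled by a nearest-feature
    rule instead of the nominal model.
    """
    if model not in MODELS:
        raise ValueError(f"unknown deformation model {model!r}")
    p = np.asarray(p, float)
    disp = np.asarray(evl_t1, float) - np.asarray(evl_t0, float)

    if model == "two_closest_vertices":
        xy = geom.azimuthal_equidistant(evl_t0, R)
        pxy = geom.azimuthal_equidistant(p, R)
        dist, idx = cKDTree(xy).query(pxy, k=2)
        if inverse_distance:
            w = 1.0 / np.maximum(dist, 1e-9)
            w = w / w.sum()
        else:
            w = np.array([0.5, 0.5])
        return w @ disp[idx], False

    if model == "cell_center_of_mass":
        if cells is None:
            raise ValueError("cell_center_of_mass needs the cell polygons")
        xy = geom.azimuthal_equidistant(evl_t0, R)
        pxy = geom.azimuthal_equidistant(p, R)
        for cyc in cells:
            if _point_in_cell(pxy, xy[list(cyc)]):
                return disp[list(cyc)].mean(axis=0), False
        # outside every cell: nearest cell centroid, flagged
        cents = np.array([xy[list(c)].mean(axis=0) for c in cells])
        k = int(np.argmin(np.linalg.norm(cents - pxy, axis=1)))
        return disp[list(cells[k])].mean(axis=0), True

    # delaunay_barycentric
    xy = geom.azimuthal_equidistant(evl_t0, R)
    tri = Delaunay(xy)
    pxy = geom.azimuthal_equidistant(p, R)
    s = int(tri.find_simplex(pxy))
    if s >= 0:
        T = tri.transform[s]
        b2 = T[:2, :] @ (pxy - T[2, :])
        gamma = np.append(b2, 1.0 - b2.sum())
        return gamma @ disp[tri.simplices[s]], False
    dist, idx = cKDTree(xy).query(pxy, k=3)
    w = 1.0 / np.maximum(dist, 1e-9)
    w = w / w.sum()
    return w @ disp[idx], True


def decompose_track(dcl_track: np.ndarray, evl_frames: np.ndarray,
                    model: str = "delaunay_barycentric",
                    cells: list[list[int]] | None = None,
                    R: float = geom.EGG_RADIUS_UM) -> DecomposedTrack:
    """Split one deep-cell track into advected and autonomous components.

    ``dcl_track`` is (n_frames, 3); ``evl_frames`` is (n_frames, n_v, 3)
    with consistent vertex identities.  The autonomous displacement is
    total − advected per frame pair, so additivity holds exactly; the
    cumulative autonomous track feeds the MSD/diffusion analysis.
    """
    track = np.asarray(dcl_track, float)
    evl = np.asarray(evl_frames, float)
    if len(track) != len(evl):
        raise ValueError("EVL frames must cover every track frame")
    n = len(track) - 1
    adv = np.empty((n, 3))
    flags = np.zeros(n, bool)
    for f in range(n):
        adv[f], flags[f] = advected_displacement(
            track[f], evl[f], evl[f + 1], model, cells=cells, R=R)
    total = np.diff(track, axis=0)
    if flags.any():
        log.warning("%d/%d frame pairs used a fallback rule", flags.sum(), n)
    return DecomposedTrack(total=total, advected=adv,
                           autonomous=total - adv, positions=track,
                           flags=flags)


def compare_models(frame0: np.ndarray, frame1: np.ndarray, field,
                   sample_points: np.ndarray,
                   cells: list[list[int]] | None = None,
                   R: float = geom.EGG_RADIUS_UM) -> dict[str, float]:
    """Mean absolute error of each deformation model against a known field.

    ``field(points)`` returns the true displacement of any frame-0 surface
    point (see ``synthetic.make_deformation_scenario``); the error is the
    mean Euclidean norm of (predicted − true) over the sample points.
    Interpolation between vertices tends to underestimate the deformation
    of an expanding sheet, so errors are non-zero even for the best model.
    """
    truth = field(sample_points)
    out: dict[str, float] = {}
    for model in MODELS:
        errs = np.empty(len(sample_points))
        for i, p in enumerate(sample_points):
            pred, _ = advected_displacement(p, frame0, frame1, model,
                                            cells=cells, R=R)
            errs[i] = np.linalg.norm(pred - truth[i])
        out[model] = float(errs.mean())
    return out
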