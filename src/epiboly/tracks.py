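"""Tidy track tables and their file formats.

A *track table* is the shared currency of the package: one row per entity
per frame, with columns ``frame`` (int), ``id`` (entity id), ``layer``
(``EVL_vertex``, ``DCL`` or ``EVL_cell``), ``x, y, z`` (μm, egg-centred)
and optionally ``radius``, ``area`` (μm²) and ``cell_id`` (polygon
membership).  The simulator writes them, the synthetic generators emulate
them, and all analytics consume them.  Stored as CSV (small runs) or HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

REQUIRED = ["frame", "id", "layer", "x", "y", "z"]
OPTIONAL = ["radius", "area", "cell_id"]


def validate_tracks(tracks: pd.DataFrame) -> None:
    """Check track-table invariants; raise ValueError on violation."""
    missing = [c for c in REQUIRED if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    if tracks.duplicated(["frame", "id", "layer"]).any():
        raise ValueError("(frame, id, layer) must be unique")
    if not np.isfinite(tracks[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("non-finite positions in track table")


def positions(tracks: pd.DataFrame, frame: int | None = None,
              layer: str | None = None) -> np.ndarray:
    """(n, 3) position array for one frame/layer selection, sorted by id."""
    t = tracks
    if frame is not None:
        t = t[t["frame"] == frame]
    if layer is not None:
        t = t[t["layer"] == layer]
    return t.sort_values("id")[["x", "y", "z"]].to_numpy()


def track_matrix(tracks: pd.DataFrame, layer: str = "DCL",
                 require_full: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Reshape a layer into a (n_frames, n_tracks, 3) array.

    Returns (ids, array).  With ``require_full`` only entities present in
    every frame are kept (e.g. daughters appearing mid-run are dropped).
    """
    t = tracks[tracks["layer"] == layer]
    frames = np.sort(t["frame"].unique())
    counts = t.groupby("id")["frame"].size()
    ids = counts[counts == len(frames)].index.to_numpy() if require_full \
        else np.sort(t["id"].unique())
    sub = t[t["id"].isin(ids)].sort_values(["frame", "id"])
    arr = sub[["x", "y", "z"]].to_numpy().reshape(len(frames), len(ids), 3)
    return np.sort(ids), arr


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    validate_tracks(tracks)
    tracks.to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    tracks = pd.read_csv(path)
    validate_tracks(tracks)
    return tracks


def write_tracks_hdf5(tracks: pd.DataFrame, path: str | Path,
                      cells: list[list[int]] | None = None) -> None:
    """Single-container HDF5 output for large runs.

    Columns are stored as datasets under /tracks; EVL cell polygons (vertex
    id cycles) go to /cells as a JSON attribute, matching the CSV + JSON
    pair for small runs.
    """
    validate_tracks(tracks)
    with h5py.File(path, "w") as f:
        grp = f.create_group("tracks")
        for col in tracks.columns:
            data = tracks[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            grp.create_dataset(col, data=data)
        if cells is not None:
            f.attrs["cells"] = json.dumps([list(map(int, c)) for c in cells])


def read_tracks_hdf5(path: str | Path
                     ) -> tuple[pd.DataFrame, list[list[int]] | None]:
    with h5py.File(path, "r") as f:
        cols = {}
        for col, ds in f["tracks"].items():
            arr = ds[()]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            cols[col] = arr
        cells = json.loads(f.attrs["cells"]) if "cells" in f.attrs else None
    tracks = pd.DataFrame(cols)
    validate_tracks(tracks)
    return tracks, cells


def write_rotations_json(rotations: list[np.ndarray],
                         path: str | Path) -> None:
    """Per-frame drift-correction rotations as frame → quaternion (x,y,z,w)."""
    from scipy.spatial.transform import Rotation

    out = {str(f): Rotation.from_matrix(M).as_quat().tolist()
           for f, M in enumerate(rotations)}
    Path(path).write_text(json.dumps(out))


def read_rotations_json(path: str | Path) -> list[np.ndarray]:
    from scipy.spatial.transform import Rotation

    d = json.loads(Path(path).read_text())
    return [Rotation.from_quat(d[k]).as_matrix()
            for k in sorted(d, key=int)]


def write_cells_json(cells: list[list[int]], path: str | Path) -> None:
    Path(path).write_text(json.dumps({str(i): list(map(int, c))
                                      for i, c in enumerate(cells)}))


def read_cells_json(path: str | Path) -> list[list[int]]:
    d = json.loads(Path(path).read_text())
    return [d[k] for k in sorted(d, key=int)]
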