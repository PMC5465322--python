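"""Cell-shape indices and protrusion detection on label masks.

Shape is summarised by the principal axes of the spacing-aware second-order
moment tensor of a labelled region: axis magnitudes λ1 ≥ λ2 ≥ λ3 (square
roots of the eigenvalues, i.e. lengths rather than variances) and the
derived indices

* elongation = 1 − λ2/λ1
* flatness  = 1 − λ3/λ2
* entropy   = −Σ λ′ᵢ log λ′ᵢ with λ′ᵢ = λᵢ/Σλ (max log 3 when isotropic)
* eccentricity = focal distance over major axis of the same-moments ellipse

Protrusions are connected components of (membrane mask − body mask) that
touch the cell body.  Components above 1.1 μm² are kept and classified by a
fixed cascade: eccentricity > 0.97 → elongated; else solidity > 0.65 →
round; else multiple elongated.  Elongated protrusions get an orientation:
the angle of their base (contact centroid) relative to the cell centre of
mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

AREA_THRESHOLD_UM2 = 1.1
ECCENTRICITY_THRESHOLD = 0.97
SOLIDITY_THRESHOLD = 0.65


@dataclass(frozen=True)
class ShapeIndices:
    lambda1: float
    lambda2: float
    lambda3: float        # NaN for 2D masks
    elongation: float     # in [0, 1]
    flatness: float       # in [0, 1]; NaN for 2D
    entropy: float        # in [0, log ndim]
    eccentricity: float   # in [0, 1)


def shape_indices(mask: np.ndarray, label: int,
                  spacing: tuple[float, ...] | None = None) -> ShapeIndices:
    """Second-moment shape descriptors of one labelled region.

    ``spacing`` gives the physical voxel size per axis in μm (defaults to
    isotropic 1 μm).  Works on 2D and 3D masks; for 2D, λ3 and flatness are
    NaN and the entropy runs over two axes.
    """
    mask = np.asarray(mask)
    if mask.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    spacing = np.ones(mask.ndim) if spacing is None \
        else np.asarray(spacing, float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    coords = np.argwhere(mask == label) * spacing
    if len(coords) == 0:
        raise ValueError(f"label {label} absent from mask")
    if len(coords) < 10:
        raise ValueError(f"label {label} too small ({len(coords)} voxels)")
    cov = np.cov((coords - coords.mean(axis=0)).T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.sqrt(np.clip(eig, 0.0, None))
    lam_prime = lam / lam.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.sum(np.where(lam_prime > 0,
                                     lam_prime * np.log(lam_prime), 0.0)))
    ecc = float(np.sqrt(max(0.0, 1.0 - (lam[1] / lam[0]) ** 2))) \
        if lam[0] > 0 else 0.0
    if mask.ndim == 2:
        return ShapeIndices(lambda1=lam[0], lambda2=lam[1], lambda3=np.nan,
                            elongation=1.0 - lam[1] / lam[0],
                            flatness=np.nan, entropy=ent, eccentricity=ecc)
    return ShapeIndices(lambda1=lam[0], lambda2=lam[1], lambda3=lam[2],
                        elongation=1.0 - lam[1] / lam[0],
                        flatness=1.0 - lam[2] / lam[1],
                        entropy=ent, eccentricity=ecc)


@dataclass(frozen=True)
class Protrusion:
    area: float                      # μm²
    kind: str                        # elongated | round | multiple_elongated
    eccentricity: float
    solidity: float
    base: tuple[float, float]        # contact centroid, μm (row, col)
    orientation: float               # rad in [−π, π], base vs cell centre


def detect_protrusions(body_mask: np.ndarray, membrane_mask: np.ndarray,
                       spacing: tuple[float, float] = (1.0, 1.0)
                       ) -> list[Protrusion]:
    """Detect and classify membrane protrusions around a cell body (2D).

    Candidate objects are 8-connected components of membrane − body that
    touch the body; components at or below 1.1 μm² are discarded, the rest
    classified by the eccentricity/solidity cascade.  Orientation is the
    angle of (base − cell centre of mass) in physical coordinates, with the
    image row axis as y.
    """
    body = np.asarray(body_mask).astype(bool)
    mem = np.asarray(membrane_mask).astype(bool)
    if body.ndim != 2 or mem.shape != body.shape:
        raise ValueError("expect aligned 2D body and membrane masks")
    sp = np.asarray(spacing, float)
    px_area = float(sp.prod())
    candidates = mem & ~body
    struct = ndimage.generate_binary_structure(2, 2)  # 8-connectivity
    labels, n = ndimage.label(candidates, structure=struct)
    if n == 0:
        return []
    body_halo = ndimage.binary_dilation(body, structure=struct)
    centre = np.array(ndimage.center_of_mass(body)) * sp
    out: list[Protrusion] = []
    for prop in regionprops(labels):
        comp = labels == prop.label
        contact = comp & body_halo & ~body
        if not contact.any():
            continue  # floating object, not a protrusion
        area = prop.num_pixels * px_area
        if area <= AREA_THRESHOLD_UM2:
            continue
        ecc = prop.eccentricity
        sol = prop.solidity
        if ecc > ECCENTRICITY_THRESHOLD:
            kind = "elongated"
        elif sol > SOLIDITY_THRESHOLD:
            kind = "round"
        else:
            kind = "multiple_elongated"
        base = np.array(ndimage.center_of_mass(contact)) * sp
        vec = base - centre
        orientation = float(np.arctan2(vec[0], vec[1]))  # (row→y, col→x)
        out.append(Protrusion(area=area, kind=kind, eccentricity=float(ecc),
                              solidity=float(sol),
                              base=(float(base[0]), float(base[1])),
                              orientation=orientation))
    return out


def read_mask(path, sidecar=None):
    """Load a label mask from TIFF with spacing from a sidecar JSON.

    The sidecar (default ``<path>.json``) holds ``{"spacing": [...]}`` in
    μm per axis; returns ``(mask, spacing)`` with spacing None if no
    sidecar exists.
    """
    import json
    from pathlib import Path

    import tifffile

    mask = tifffile.imread(path)
    side = Path(sidecar) if sidecar else Path(str(path) + ".json")
    spacing = None
    if side.exists():
        spacing = tuple(json.loads(side.read_text())["spacing"])
    return mask, spacing


def eccentricity_timecourse(masks: list[np.ndarray | None], label: int,
                            spacing: tuple[float, ...] | None = None
                            ) -> np.ndarray:
    """Per-frame eccentricity of a tracked label; NaN for missing frames.

    Deep cells elongate transiently when the EVL above them contracts
    (e.g. around an extruding EVL cell); this series is the input to that
    quantification.
    """
    out = np.full(len(masks), np.nan)
    for f, m in enumerate(masks):
        if m is None or not np.any(np.asarray(m) == label):
            continue
        out[f] = shape_indices(m, label, spacing).eccentricity
    return out
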