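"""EVL vertex-spring mesh: the substrate tissue of the model.

The enveloping layer (EVL) is represented by the vertices of its polygonal
cells, living on the egg sphere.  Vertices are connected by two families of
harmonic springs: *edge* springs between consecutive vertices of a cell
cycle, and *opposite-vertex* springs across each cell, which prevent a cell
from over-expanding while its border is pulled vegetally.  Vertices on the
epibolic margin (the free vegetal border) are flagged; they are the ones
driven at constant speed during epiboly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geom


@dataclass
class EVLMesh:
    """Polygonal EVL tessellation with spring topology.

    Attributes
    ----------
    vertices : (n_v, 3) float array
        Vertex positions on the sphere, μm.
    cells : list of list of int
        Ordered (counter-clockwise seen from outside) vertex cycles, one per
        EVL cell.
    is_border : (n_v,) bool array
        True for vertices on the free (vegetal) epibolic margin.
    springs : (n_s, 2) int array
        Vertex index pairs; edge springs first, then opposite-vertex springs.
    rest_lengths : (n_s,) float array
        Spring rest lengths, μm (chord lengths at mesh construction).
    spring_weights : (n_s,) float array
        Relative spring strength; 1 for edge springs, 1 (or 1/2 for the two
        half-weight pairs of odd cycles) for opposite springs.
    R : float
        Sphere radius, μm.
    """

    vertices: np.ndarray
    cells: list[list[int]]
    is_border: np.ndarray
    springs: np.ndarray = field(default=None)  # type: ignore[assignment]
    rest_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]
    spring_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    R: float = geom.EGG_RADIUS_UM

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.is_border = np.asarray(self.is_border, bool)
        if self.springs is None:
            self._build_springs()
        else:
            self.springs = np.asarray(self.springs, int)
            self.rest_lengths = np.asarray(self.rest_lengths, float)
            self.spring_weights = np.asarray(self.spring_weights, float)

    # -- topology -----------------------------------------------------------

    def _build_springs(self) -> None:
        """Derive edge and opposite-vertex springs from the cell cycles.

        Opposite pairs for a cycle of length m are (k, k+⌊m/2⌋); for odd m
        each vertex has two nearest-to-opposite partners, taken at half
        weight so the total across-cell stiffness matches the even case.
        """
        edge: set[tuple[int, int]] = set()
        opp: dict[tuple[int, int], float] = {}
        for cyc in self.cells:
            m = len(cyc)
            if m < 3:
                raise ValueError("cell cycles need at least 3 vertices")
            if len(set(cyc)) != m:
                raise ValueError("cell cycle is not simple (repeated vertex)")
            for k in range(m):
                i, j = cyc[k], cyc[(k + 1) % m]
                edge.add((min(i, j), max(i, j)))
            half = m // 2
            for k in range(m):
                if m % 2 == 0:
                    pairs = [(cyc[k], cyc[(k + half) % m], 1.0)]
                else:
                    pairs = [(cyc[k], cyc[(k + half) % m], 0.5),
                             (cyc[k], cyc[(k + half + 1) % m], 0.5)]
                for i, j, w in pairs:
                    key = (min(i, j), max(i, j))
                    if key not in edge:
                        opp[key] = max(opp.get(key, 0.0), w)
        pairs_arr = np.array(sorted(edge) + sorted(opp), int)
        weights = np.concatenate([np.ones(len(edge)),
                                  np.array([opp[k] for k in sorted(opp)])])
        self.springs = pairs_arr
        self.spring_weights = weights
        d = self.vertices[pairs_arr[:, 0]] - self.vertices[pairs_arr[:, 1]]
        self.rest_lengths = np.linalg.norm(d, axis=1)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def cell_polygon(self, c: int) -> np.ndarray:
        return self.vertices[self.cells[c]]

    def cell_areas(self) -> np.ndarray:
        """Spherical polygon area of every cell, μm²."""
        return np.array([geom.spherical_polygon_area(self.cell_polygon(c), self.R)
                         for c in range(len(self.cells))])

    def border_arcs(self) -> tuple[np.ndarray, np.ndarray]:
        """Deduplicated cell-border segments as endpoint arrays (a, b).

        These arcs are the EVL cell membranes: the support of the
        border-attraction potential and the reference set for DCL
        distance-to-border measurements.
        """
        seen: set[tuple[int, int]] = set()
        for cyc in self.cells:
            for k in range(len(cyc)):
                i, j = cyc[k], cyc[(k + 1) % len(cyc)]
                seen.add((min(i, j), max(i, j)))
        idx = np.array(sorted(seen), int)
        return self.vertices[idx[:, 0]], self.vertices[idx[:, 1]]

    def border_edge_index(self) -> np.ndarray:
        """(k, 2) vertex-index pairs of the deduplicated cell edges."""
        seen: set[tuple[int, int]] = set()
        for cyc in self.cells:
            for k in range(len(cyc)):
                i, j = cyc[k], cyc[(k + 1) % len(cyc)]
                seen.add((min(i, j), max(i, j)))
        return np.array(sorted(seen), int)

    def validate(self, tol: float = 1e-6) -> None:
        """Check structural invariants; raise ValueError on violation."""
        r = np.linalg.norm(self.vertices, axis=1)
        if not np.allclose(r, self.R, rtol=tol):
            raise ValueError("mesh vertices are not on the sphere")
        used = set()
        for cyc in self.cells:
            used.update(cyc)
        if used - set(range(self.n_vertices)):
            raise ValueError("cell cycle references unknown vertex")

    def copy(self) -> "EVLMesh":
        return EVLMesh(self.vertices.copy(), [list(c) for c in self.cells],
                       self.is_border.copy(), self.springs.copy(),
                       self.rest_lengths.copy(), self.spring_weights.copy(),
                       self.R)
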