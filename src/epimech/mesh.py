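"""Polygonal cell meshes with shared vertices, optionally periodic.

A :class:`Tissue` stores the apical geometry of a confluent epithelium as a
set of 2-D vertices and per-cell vertex-index loops.  Vertices shared by
three or more cells are tricellular junctions (TCJs).  Periodic tissues
carry a 2x2 box matrix (rows are the lattice vectors); cell loops are
unwrapped by minimum image around their first vertex before any geometry
is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting cell polygons."""


def as_box_matrix(box) -> np.ndarray | None:
    """Normalize a box spec ([Lx, Ly] or 2x2 matrix) to a 2x2 float array."""
    if box is None:
        return None
    b = np.asarray(box, dtype=float)
    if b.shape == (2,):
        return np.diag(b)
    if b.shape == (2, 2):
        return b.copy()
    raise ValueError(f"box must be length-2 or 2x2, got shape {b.shape}")


def polygon_area_perimeter(poly: np.ndarray) -> tuple[float, float]:
    """Area and perimeter of a simple polygon given as an (n, 2) vertex loop.

    The loop must be counter-clockwise (positive signed area), contain at
    least three distinct vertices, and be free of self-intersections.
    """
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise GeometryError(f"polygon needs >=3 2-D vertices, got shape {poly.shape}")
    if len(np.unique(poly.round(decimals=12), axis=0)) < 3:
        raise GeometryError("polygon has fewer than 3 distinct vertices")
    nxt = np.roll(poly, -1, axis=0)
    area = 0.5 * float(np.sum(poly[:, 0] * nxt[:, 1] - nxt[:, 0] * poly[:, 1]))
    if area <= 0:
        raise GeometryError(f"polygon has non-positive signed area {area:.3g} "
                            "(loops must be counter-clockwise)")
    if not LinearRing(poly).is_simple:
        raise GeometryError("polygon is self-intersecting")
    perimeter = float(np.linalg.norm(nxt - poly, axis=1).sum())
    return area, perimeter


def signed_area(poly: np.ndarray) -> float:
    nxt = np.roll(poly, -1, axis=0)
    return 0.5 * float(np.sum(poly[:, 0] * nxt[:, 1] - nxt[:, 0] * poly[:, 1]))


@dataclass
class Tissue:
    """Shared-vertex polygonal cell mesh.

    Parameters
    ----------
    vertices : (N, 2) float array
        Vertex positions.  In periodic mode these live in the box
        (fractional coordinates in [0, 1) after applying the inverse box).
    cells : list of int arrays
        Per-cell vertex-index loops, counter-clockwise after unwrapping.
    box : None, (2,) or (2, 2) array
        Periodic box; a pair is a rectangular box (Lx, Ly), a matrix has
        lattice vectors as rows.  ``None`` means a bounded tissue.
    junction_degree : optional int array
        Per-vertex count of incident cells.  If absent it is computed from
        cell incidence; pass it explicitly for fixtures or segmented data
        whose TCJ annotation differs from mesh incidence (e.g. tissue
        borders cropped out of the field of view).
    offsets : optional list of (n_i, 2) arrays
        Explicit integer lattice offsets per cell-vertex occurrence.  When
        absent they are derived by minimum-image unwrapping, which is
        exact for cells smaller than half the box; tiny periodic tissues
        (cells wrapping the torus) need them explicitly.
    """

    vertices: np.ndarray
    cells: list[np.ndarray]
    box: np.ndarray | None = None
    junction_degree: np.ndarray | None = None
    offsets: list[np.ndarray] | None = None
    _offsets: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = [np.asarray(c, dtype=int) for c in self.cells]
        self.box = as_box_matrix(self.box)
        if self.junction_degree is not None:
            self.junction_degree = np.asarray(self.junction_degree, dtype=int)
        if self.offsets is not None:
            self.offsets = [np.asarray(o, dtype=float) for o in self.offsets]

    # ------------------------------------------------------------------ sizes
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    # ----------------------------------------------------------- periodic ops
    def fractional(self) -> np.ndarray:
        """Vertex coordinates in fractional (box) units; requires a box."""
        if self.box is None:
            raise ValueError("tissue is not periodic")
        return self.vertices @ np.linalg.inv(self.box)

    def cell_offsets(self) -> list[np.ndarray]:
        """Per-cell integer lattice offsets that unwrap each loop (minimum
        image around the first vertex)."""
        if self.box is None:
            return [np.zeros((len(c), 2)) for c in self.cells]
        if self.offsets is not None:
            return self.offsets
        if self._offsets is None:
            frac = self.fractional()
            offs = []
            for loop in self.cells:
                f = frac[loop]
                o = np.zeros((len(loop), 2))
                o[1:] = -np.cumsum(np.round(np.diff(f, axis=0)), axis=0)
                offs.append(o)
            self._offsets = offs
        return self._offsets

    def cell_polygon(self, i: int) -> np.ndarray:
        """Unwrapped absolute coordinates of cell ``i`` as an (n, 2) array."""
        loop = self.cells[i]
        if self.box is None:
            return self.vertices[loop].copy()
        frac = self.fractional()
        return (frac[loop] + self.cell_offsets()[i]) @ self.box

    def cell_polygons(self) -> list[np.ndarray]:
        return [self.cell_polygon(i) for i in range(self.n_cells)]

    # -------------------------------------------------------------- topology
    def edge_map(self) -> dict[tuple, list[int]]:
        """Map from undirected edge to the list of incident cell indices.

        Keys are ``(i, j, (dx, dy))`` with i < j, where (dx, dy) is the
        periodic image offset of j relative to i along the edge: distinct
        torus edges joining the same canonical vertex pair (possible in
        very small periodic tissues) are kept distinct.
        """
        edges: dict[tuple, list[int]] = {}
        offsets = self.cell_offsets()
        for ci, (loop, offs) in enumerate(zip(self.cells, offsets)):
            for k in range(len(loop)):
                k2 = (k + 1) % len(loop)
                a, b = int(loop[k]), int(loop[k2])
                d = offs[k2] - offs[k]
                if b < a:
                    a, b, d = b, a, -d
                key = (a, b, (int(round(d[0])), int(round(d[1]))))
                edges.setdefault(key, []).append(ci)
        return edges

    def adjacency(self) -> dict[int, set[int]]:
        """Cell-cell shared-edge adjacency."""
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_cells)}
        for cs in self.edge_map().values():
            for a in cs:
                for b in cs:
                    if a != b:
                        adj[a].add(b)
        return adj

    def junction_degrees(self) -> np.ndarray:
        """Per-vertex number of incident cells (>=3 marks a TCJ)."""
        if self.junction_degree is not None:
            return self.junction_degree
        deg = np.zeros(self.n_vertices, dtype=int)
        for loop in self.cells:
            deg[loop] += 1
        return deg

    def boundary_cells(self) -> np.ndarray:
        """Boolean mask of cells owning at least one unshared edge.

        Periodic tissues have no boundary.
        """
        mask = np.zeros(self.n_cells, dtype=bool)
        if self.box is not None:
            return mask
        for cs in self.edge_map().values():
            if len(cs) == 1:
                mask[cs[0]] = True
        return mask

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        """Check the mesh invariants; raise :class:`GeometryError` on failure."""
        for i in range(self.n_cells):
            if len(self.cells[i]) < 3:
                raise GeometryError(f"cell {i} has fewer than 3 vertices")
            polygon_area_perimeter(self.cell_polygon(i))
        for key, cs in self.edge_map().items():
            if len(cs) > 2:
                raise GeometryError(f"edge {key[:2]} shared by {len(cs)} > 2 cells")
            if self.box is not None and len(cs) != 2:
                raise GeometryError(f"periodic tissue has unpaired edge {key[:2]}")
        if self.box is not None:
            frac = self.fractional()
            if not ((frac >= -1e-9) & (frac < 1 + 1e-9)).all():
                raise GeometryError("periodic vertices must lie inside the box")

    def total_cell_area(self) -> float:
        return float(sum(polygon_area_perimeter(p)[0] for p in self.cell_polygons()))

    def box_area(self) -> float:
        if self.box is None:
            raise ValueError("tissue is not periodic")
        return abs(float(np.linalg.det(self.box)))

    # ------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        d = {
            "vertices": self.vertices.tolist(),
            "cells": [c.tolist() for c in self.cells],
            "box": None if self.box is None else self.box.tolist(),
        }
        if self.junction_degree is not None:
            d["junction_degree"] = self.junction_degree.tolist()
        if self.offsets is not None:
            d["offsets"] = [o.tolist() for o in self.offsets]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Tissue":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            cells=[np.asarray(c, dtype=int) for c in d["cells"]],
            box=d.get("box"),
            junction_degree=(np.asarray(d["junction_degree"], dtype=int)
                             if d.get("junction_degree") is not None else None),
            offsets=(d["offsets"] if d.get("offsets") is not None else None),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "Tissue":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def copy(self) -> "Tissue":
        return Tissue(
            vertices=self.vertices.copy(),
            cells=[c.copy() for c in self.cells],
            box=None if self.box is None else self.box.copy(),
            junction_degree=(None if self.junction_degree is None
                             else self.junction_degree.copy()),
            offsets=(None if self.offsets is None
                     else [o.copy() for o in self.offsets]),
        )
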