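"""Cell-shape tensors, orientations and circularities.

Three characterizations of a cell's shape are supported, each a centered
second-moment tensor of a different geometric referent:

``area``
    second moment of area over the polygon interior, normalized by area
    (a uniform lamina's covariance; a w x h rectangle gives
    diag(w^2/12, h^2/12));
``perimeter``
    arc-length-weighted second moment along the boundary, about the
    boundary's line centroid;
``junction``
    unweighted second moment of the tricellular-junction (TCJ) vertices,
    about their mean.

From any of these tensors the shape orientation ``theta`` (axial, degrees
in [0, 180), measured counter-clockwise from the x axis, which is the
global stretch axis by convention) is the principal eigenvector axis, and
the circularity ``C = lambda_min / lambda_max`` ranges from 0 (straight
line) to 1 (perfect circle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import GeometryError, Tissue, polygon_area_perimeter

METHODS = ("area", "perimeter", "junction")

#: relative eigenvalue gap below which a tensor is considered isotropic
ISOTROPY_RTOL = 1e-9


@dataclass(frozen=True)
class ShapeDescriptor:
    """Orientation and circularity derived from one shape tensor."""

    method: str
    theta: float          # axial degrees in [0, 180)
    circularity: float    # in [0, 1]
    eigvals: tuple[float, float]  # (lambda_max, lambda_min)
    degenerate: bool = False      # isotropic tensor: theta undefined, reported 0
    fallback: bool = False        # junction method fell back to all vertices


@dataclass(frozen=True)
class DivisionEvent:
    """A single cell division scored at anaphase.

    ``theta_d`` is the axial angle (degrees in [0, 180)) of the segment
    joining the daughter nuclei; ``t_neb`` is the time of nuclear envelope
    breakdown in minutes.
    """

    cell_id: int
    t_neb: float
    daughter_a: tuple[float, float]
    daughter_b: tuple[float, float]

    @property
    def theta_d(self) -> float:
        return division_angle(self.daughter_a, self.daughter_b)


# --------------------------------------------------------------------- angles

def fold_axial(theta: float) -> float:
    """Fold any angle in degrees onto the axial range [0, 180)."""
    return float(np.mod(theta, 180.0))


def fold_axial_difference(theta1, theta2):
    """Smallest axial difference between two orientations, in [0, 90].

    Orientations are headless axes: theta and theta + 180 are identical.
    Accepts scalars or arrays.
    """
    d = np.abs(np.mod(np.asarray(theta1, float) - np.asarray(theta2, float), 180.0))
    out = np.minimum(d, 180.0 - d)
    return float(out) if out.ndim == 0 else out


def division_angle(daughter_a, daughter_b) -> float:
    """Axial angle of the daughter-daughter segment, degrees in [0, 180)."""
    a = np.asarray(daughter_a, float)
    b = np.asarray(daughter_b, float)
    d = b - a
    if not np.any(d):
        raise GeometryError("daughter positions coincide")
    return fold_axial(np.degrees(np.arctan2(d[1], d[0])))


# -------------------------------------------------------------- shape tensors

def _pair_moment(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """sum_k w_k * (aa^T + bb^T + (ab^T + ba^T)/2), vectorized."""
    aa = np.einsum("k,ki,kj->ij", w, a, a)
    bb = np.einsum("k,ki,kj->ij", w, b, b)
    ab = np.einsum("k,ki,kj->ij", w, a, b)
    return aa + bb + 0.5 * (ab + ab.T)


def _area_tensor(poly: np.ndarray) -> np.ndarray:
    """Second moment of area about the area centroid, normalized by area."""
    nxt = np.roll(poly, -1, axis=0)
    cross = poly[:, 0] * nxt[:, 1] - nxt[:, 0] * poly[:, 1]
    area = 0.5 * cross.sum()
    centroid = ((poly + nxt) * cross[:, None]).sum(axis=0) / (6.0 * area)
    a = poly - centroid
    b = nxt - centroid
    crz = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    # triangle (0, a, b): integral of r r^T dA = crz * (aa + bb + (ab+ba)/2) / 12
    return _pair_moment(a, b, crz / 12.0) / area


def _perimeter_tensor(poly: np.ndarray) -> np.ndarray:
    """Arc-length second moment about the boundary line centroid."""
    nxt = np.roll(poly, -1, axis=0)
    ln = np.linalg.norm(nxt - poly, axis=1)
    L = ln.sum()
    centroid = (0.5 * (poly + nxt) * ln[:, None]).sum(axis=0) / L
    a = poly - centroid
    b = nxt - centroid
    # segment a->b: integral of r r^T ds = |l| * (aa + bb + (ab+ba)/2) / 3
    return _pair_moment(a, b, ln / 3.0) / L


def _vertex_tensor(points: np.ndarray) -> np.ndarray:
    d = points - points.mean(axis=0)
    return d.T @ d / len(points)


def shape_tensor(poly: np.ndarray, method: str,
                 tcj_mask: np.ndarray | None = None,
                 _validate: bool = True) -> tuple[np.ndarray, bool]:
    """Centered second-moment tensor of a cell polygon.

    Parameters
    ----------
    poly : (n, 2) array
        Unwrapped counter-clockwise vertex loop.
    method : {"area", "perimeter", "junction"}
    tcj_mask : bool array, optional
        Marks which vertices of the loop are tricellular junctions (only
        used by the junction method; all vertices assumed TCJs if omitted).

    Returns
    -------
    tensor : (2, 2) symmetric PSD array
    fallback : bool
        True when the junction method had fewer than 3 TCJs and fell back
        to using all vertices.
    """
    poly = np.asarray(poly, dtype=float)
    if _validate:
        polygon_area_perimeter(poly)
    if not np.all(np.isfinite(poly)):
        raise GeometryError("non-finite vertex coordinates")
    if method == "area":
        return _area_tensor(poly), False
    if method == "perimeter":
        return _perimeter_tensor(poly), False
    if method == "junction":
        if tcj_mask is None:
            return _vertex_tensor(poly), False
        tcj_mask = np.asarray(tcj_mask, dtype=bool)
        if tcj_mask.sum() >= 3:
            return _vertex_tensor(poly[tcj_mask]), False
        return _vertex_tensor(poly), True
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def descriptor_from_tensor(tensor: np.ndarray, method: str = "area",
                           fallback: bool = False) -> ShapeDescriptor:
    """Orientation and circularity from a symmetric PSD shape tensor.

    ``theta`` is the axis of the largest eigenvalue folded to [0, 180);
    ``circularity`` is lambda_min / lambda_max.  An isotropic tensor has
    undefined orientation: it is reported as theta = 0 with the
    ``degenerate`` flag set (downstream statistics exclude such cells).
    A zero tensor (single point) is treated as a degenerate circle (C = 1).
    """
    t = np.asarray(tensor, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("shape tensor has non-finite entries")
    if not np.allclose(t, t.T, atol=1e-12 * max(1.0, np.abs(t).max())):
        raise ValueError("shape tensor must be symmetric")
    w, v = np.linalg.eigh(t)
    lmin, lmax = float(w[0]), float(w[1])
    if lmin < -1e-12 * max(lmax, 1.0):
        raise ValueError("shape tensor must be positive semi-definite")
    lmin = max(lmin, 0.0)
    if lmax <= 0.0:
        return ShapeDescriptor(method, 0.0, 1.0, (0.0, 0.0), degenerate=True,
                               fallback=fallback)
    circ = lmin / lmax
    if lmax - lmin <= ISOTROPY_RTOL * lmax:
        return ShapeDescriptor(method, 0.0, 1.0, (lmax, lmin), degenerate=True,
                               fallback=fallback)
    e = v[:, 1]
    theta = fold_axial(np.degrees(np.arctan2(e[1], e[0])))
    return ShapeDescriptor(method, theta, circ, (lmax, lmin), fallback=fallback)


def cell_shape(poly: np.ndarray, method: str,
               tcj_mask: np.ndarray | None = None,
               _validate: bool = True) -> ShapeDescriptor:
    """Shape descriptor of one cell polygon for one method."""
    tensor, fb = shape_tensor(poly, method, tcj_mask, _validate=_validate)
    return descriptor_from_tensor(tensor, method, fallback=fb)


# ------------------------------------------------------------- tissue tables

def characterize_tissue(tissue: Tissue) -> pd.DataFrame:
    """Per-cell shape table: area, perimeter and the three (theta, C) pairs.

    Junction tensors use TCJ vertices (junction degree >= 3).  Cells on a
    bounded tissue's border use all their vertices (their mesh-derived
    junction degrees undercount shared cells) and are flagged
    ``boundary``; an explicitly annotated ``junction_degree`` always takes
    precedence.  Columns ``degenerate_*`` and ``fallback_J`` carry the
    per-method flags.
    """
    deg = tissue.junction_degrees()
    boundary = tissue.boundary_cells()
    annotated = tissue.junction_degree is not None
    rows = []
    for i in range(tissue.n_cells):
        poly = tissue.cell_polygon(i)
        area, perim = polygon_area_perimeter(poly)
        row = {"cell_id": i, "area": area, "perimeter": perim,
               "boundary": bool(boundary[i])}
        if boundary[i] and not annotated:
            tcj_mask = None
        else:
            tcj_mask = deg[tissue.cells[i]] >= 3
        for method, col in (("area", "A"), ("perimeter", "P"), ("junction", "J")):
            d = cell_shape(poly, method, tcj_mask if method == "junction" else None,
                           _validate=False)
            row[f"theta_{col}"] = d.theta
            row[f"C_{col}"] = d.circularity
            row[f"degenerate_{col}"] = d.degenerate
            if method == "junction":
                row["fallback_J"] = d.fallback
        rows.append(row)
    return pd.DataFrame(rows)
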