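"""Vertex-model inference of relative cell stress.

Per-cell mechanics follow the dimensionless vertex-model energy

    u = 1/2 (A - 1)^2 + 1/2 Gamma L^2 + 1/2 Lambda L,

with areas scaled by the preferred area A0 and lengths by sqrt(A0).  The
cell pressure is P = A - 1 and the (cell-borne) edge tension is
T = Gamma L + Lambda / 2.  The energy-derived (virial) cell stress, i.e.
the strain derivative of u per unit area, is

    sigma_v = (A - 1) I + (T / A) sum_edges |l| lhat lhat^T,

whose isotropic part is the effective pressure

    Peff = (A - 1) + Gamma L^2 / (2 A) + Lambda L / (4 A),

positive for cells under net tension, negative under net compression.

The cell stress *read-out* used throughout the package projects the
virial onto the eigenframe of the junction shape tensor: trace (hence
Peff) and the in-frame deviatoric component are preserved, and the
principal stress axis is by construction coaxial with the TCJ shape axis
theta_J.  The shear stress xi is the deviatoric eigenvalue of that
tensor.  The raw virial tensor remains available (``virial_stress_tensor``)
as the mechanical reference; tissue-level stress aggregates virial
tensors, so a tissue relaxed at zero global stress reports a vanishing
stress tensor exactly.

Only relative (dimensionless) stresses are inferred; no absolute
calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mesh import GeometryError, Tissue, polygon_area_perimeter
from .shape import ISOTROPY_RTOL, fold_axial, shape_tensor

TENSION = "tension"
COMPRESSION = "compression"
BOUNDARY = "boundary"


class CalibrationError(RuntimeError):
    """Raised when the preferred-area fit cannot bracket a root."""


@dataclass
class MechParams:
    """Vertex-model parameters: line tension Lambda, perimeter stiffness
    Gamma (both dimensionless) and preferred area A0 (area units).

    Defaults are the parameters used for all tissue simulations,
    (Lambda, Gamma) = (-0.259, 0.172).
    """

    lam: float = -0.259
    gamma: float = 0.172
    a0: float = 1.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"Gamma must be positive, got {self.gamma}")
        if self.a0 <= 0:
            raise ValueError(f"A0 must be positive, got {self.a0}")


@dataclass(frozen=True)
class CellStress:
    """Per-cell stress read-out (all dimensionless)."""

    peff: float          # effective pressure, isotropic part
    xi: float            # deviatoric eigenvalue (shear stress)
    theta_sigma: float   # principal stress axis, axial degrees
    tensor: np.ndarray   # 2x2 symmetric
    degenerate: bool = False  # no well-defined axis (isotropic junction tensor)


@dataclass(frozen=True)
class TissueStress:
    p_tis: float
    tensor: np.ndarray


def effective_pressure(area: float, perimeter: float, params: MechParams) -> float:
    """Effective pressure of a cell with the given physical area/perimeter.

    Area is nondimensionalized by ``params.a0`` and perimeter by
    ``sqrt(params.a0)``; Peff > 0 means net tension.
    """
    if area <= 0 or perimeter <= 0:
        raise GeometryError("area and perimeter must be positive")
    a = area / params.a0
    ln = perimeter / np.sqrt(params.a0)
    return float((a - 1.0) + params.gamma * ln**2 / (2.0 * a)
                 + params.lam * ln / (4.0 * a))


def virial_stress_tensor(poly: np.ndarray, params: MechParams) -> np.ndarray:
    """Energy-derived (virial) cell stress tensor, dimensionless.

    Equals (1/A) dU/d(strain) for an affine deformation of the cell; its
    half-trace is exactly ``effective_pressure``.
    """
    area, perim = polygon_area_perimeter(poly)
    poly = np.asarray(poly, float) / np.sqrt(params.a0)
    a = area / params.a0
    ln = perim / np.sqrt(params.a0)
    nxt = np.roll(poly, -1, axis=0)
    e = nxt - poly
    el = np.linalg.norm(e, axis=1)
    m = (e.T * (1.0 / el)) @ e  # sum over edges of |l| lhat lhat^T
    tension = params.gamma * ln + 0.5 * params.lam
    return (a - 1.0) * np.eye(2) + (tension / a) * m


def cell_stress_tensor(poly: np.ndarray, params: MechParams,
                       tcj_mask: np.ndarray | None = None) -> CellStress:
    """Cell stress in the junction-shape eigenframe.

    The virial stress is projected onto the eigenframe of the junction
    (TCJ) shape tensor: the returned tensor has the same trace (Peff) and
    its principal axis coincides with theta_J.  When the junction tensor
    is isotropic (no preferred shape axis) the virial's own eigenframe is
    used and the result is flagged degenerate.
    """
    sig_v = virial_stress_tensor(poly, params)
    peff = 0.5 * float(np.trace(sig_v))
    jt, _ = shape_tensor(poly, "junction", tcj_mask)
    w, v = np.linalg.eigh(jt)
    degenerate = (w[1] <= 0) or (w[1] - w[0] <= ISOTROPY_RTOL * w[1])
    if degenerate:
        w2, v = np.linalg.eigh(sig_v)
    e1 = v[:, 1]  # major axis
    e2 = v[:, 0]
    xi = 0.5 * float(e1 @ sig_v @ e1 - e2 @ sig_v @ e2)
    tensor = peff * np.eye(2) + xi * (np.outer(e1, e1) - np.outer(e2, e2))
    theta = fold_axial(np.degrees(np.arctan2(e1[1], e1[0])))
    if degenerate and abs(xi) <= 1e-12 * max(1.0, abs(peff)):
        theta = 0.0
    return CellStress(peff=peff, xi=xi, theta_sigma=theta, tensor=tensor,
                      degenerate=bool(degenerate))


def classify_tension(peff: float) -> str:
    """Tension/compression classification; exactly zero Peff sits on the
    boundary and is flagged (excluded from tension/compression counts)."""
    if not np.isfinite(peff):
        raise ValueError("peff must be finite")
    if peff > 0:
        return TENSION
    if peff < 0:
        return COMPRESSION
    return BOUNDARY


def tissue_stress(tissue: Tissue, params: MechParams,
                  weighting: str = "area") -> TissueStress:
    """Tissue-level stress: weighted mean of per-cell virial tensors.

    ``weighting="area"`` (default) weights each cell by its area, so the
    aggregate equals the strain derivative of the total energy per unit
    tissue area; ``"mean"`` is the unweighted cell mean.
    """
    if tissue.n_cells == 0:
        raise ValueError("empty tissue")
    if weighting not in ("area", "mean"):
        raise ValueError(f"unknown weighting {weighting!r}")
    total = np.zeros((2, 2))
    wsum = 0.0
    for poly in tissue.cell_polygons():
        area, _ = polygon_area_perimeter(poly)
        w = area / params.a0 if weighting == "area" else 1.0
        total += w * virial_stress_tensor(poly, params)
        wsum += w
    tensor = total / wsum
    return TissueStress(p_tis=0.5 * float(np.trace(tensor)), tensor=tensor)


def fit_preferred_area(tissue: Tissue, lam: float = -0.259, gamma: float = 0.172,
                       weighting: str = "area",
                       rtol: float = 1e-8) -> tuple[float, float]:
    """Calibrate the preferred area A0 so the tissue pressure vanishes.

    For Lambda <= 0 the tissue pressure is strictly decreasing in A0, so
    the root is unique; it is bracketed in [1e-3, 1e3] x (mean cell area)
    and found by Brent's method to relative tolerance ``rtol``.

    Returns ``(a0, p_tis_at_a0)``.  Raises :class:`CalibrationError` if
    the bracket contains no sign change.
    """
    geoms = [polygon_area_perimeter(p) for p in tissue.cell_polygons()]
    areas = np.array([g[0] for g in geoms])
    perims = np.array([g[1] for g in geoms])
    wts = areas if weighting == "area" else np.ones_like(areas)

    def p_tis(a0: float) -> float:
        a = areas / a0
        ln = perims / np.sqrt(a0)
        peff = (a - 1.0) + gamma * ln**2 / (2.0 * a) + lam * ln / (4.0 * a)
        return float(np.average(peff, weights=wts))

    abar = float(areas.mean())
    lo, hi = 1e-3 * abar, 1e3 * abar
    flo, fhi = p_tis(lo), p_tis(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"no sign change of Ptis in [{lo:.3g}, {hi:.3g}]: "
            f"Ptis({lo:.3g})={flo:.3g}, Ptis({hi:.3g})={fhi:.3g}")
    a0 = brentq(p_tis, lo, hi, rtol=rtol, xtol=1e-300)
    return float(a0), p_tis(float(a0))
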