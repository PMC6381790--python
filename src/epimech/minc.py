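"""Length-dependent microtubule-pulling torque model of spindle orientation.

The model places a mitotic spindle (two poles separated along a candidate
axis) at the cell's area centroid.  Astral microtubules radiate from each
pole over the half-fan facing away from the spindle body (uniformly
spaced ray directions within +-90 degrees of the pole's outward axis) to
the cell boundary, and exert pulling forces on the pole that grow with
microtubule length as l**beta (beta = 3 by default).  The net torque
about the centroid rotates the spindle; division is predicted along the
torque-free axis that is stable and minimizes the rotational potential
-integral(torque dphi).

The half-fan geometry matters: for a full isotropic fan the polar
first-moment identity integral(l^3 dhat dpsi) = 3 A (centroid - pole)
makes the net pulling force of every pole point exactly at the area
centroid when beta = 3, so the torque vanishes identically for any cell
shape and the model carries no signal.  Restricting each aster to the
outward half-fan (the inward directions are occupied by the spindle
proper) recovers the long-axis rule.

Cells without a usable axis are flagged degenerate: either the torque
profile is flat (near-circles), or symmetry leaves several stable zeros
with exactly tied potentials (regular polygons, e.g. the diagonals of a
square), which no torque argument can distinguish.  A tie may instead be
broken toward a caller-supplied reference axis (e.g. the junction shape
axis), in which case the prediction is marked ``tie_broken``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .mesh import GeometryError, polygon_area_perimeter


@dataclass
class MincConfig:
    beta: float = 3.0                 # force ~ length**beta
    n_rays: int = 180                 # astral microtubules per spindle pole
    pole_half_separation: float = 0.25  # fraction of mean centroid-vertex distance
    angle_grid: float = 1.0           # torque-scan resolution, degrees
    degeneracy_rtol: float = 1e-6     # |torque| threshold relative to scale

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_rays < 36:
            raise ValueError("need at least 36 rays per pole")
        if not 0 < self.pole_half_separation < 1:
            raise ValueError("pole_half_separation must be in (0, 1)")


@dataclass(frozen=True)
class MincPrediction:
    theta_minc: float            # axial degrees in [0, 180)
    torque_profile: np.ndarray   # (n_grid, 2): angle deg, torque
    degenerate: bool
    pole_shrunk: bool = False    # pole_half_separation auto-reduced
    tie_broken: bool = False     # symmetric tie resolved toward tie_axis


def _area_centroid(poly: np.ndarray) -> np.ndarray:
    nxt = np.roll(poly, -1, axis=0)
    cross = poly[:, 0] * nxt[:, 1] - nxt[:, 0] * poly[:, 1]
    area = 0.5 * cross.sum()
    return ((poly + nxt) * cross[:, None]).sum(axis=0) / (6.0 * area)


def ray_lengths(poly: np.ndarray, origin: np.ndarray,
                directions: np.ndarray) -> np.ndarray:
    """First-intersection distances from an interior origin to the boundary.

    ``directions`` is (m, 2) of unit vectors; returns (m,) positive
    distances.  The origin must lie strictly inside the polygon.
    """
    poly = np.asarray(poly, float)
    origin = np.asarray(origin, float)
    polygon_area_perimeter(poly)
    if not Polygon(poly).contains(Point(origin)):
        raise GeometryError("ray origin must lie strictly inside the polygon")
    directions = np.asarray(directions, float)
    p = poly - origin                      # (n, 2) edge starts
    q = np.roll(poly, -1, axis=0) - origin  # edge ends
    e = q - p
    # solve t*d = p + s*e  =>  t = cross(p, e)/cross(d, e), s = cross(p, d)/cross(d, e)
    d = directions
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p[None, :, 0] * e[None, :, 1] - p[None, :, 1] * e[None, :, 0]) / denom
        s = (p[None, :, 0] * d[:, None, 1] - p[None, :, 1] * d[:, None, 0]) / denom
    valid = (np.abs(denom) > 1e-300) & (s >= -1e-12) & (s <= 1 + 1e-12) & (t > 1e-12)
    t = np.where(valid, t, np.inf)
    lengths = t.min(axis=1)
    if not np.all(np.isfinite(lengths)):
        raise GeometryError("a ray failed to intersect the boundary")
    return lengths


def _pole_positions(poly: np.ndarray, phi_rad: float, config: MincConfig):
    centroid = _area_centroid(poly)
    rbar = float(np.linalg.norm(poly - centroid, axis=1).mean())
    u = np.array([np.cos(phi_rad), np.sin(phi_rad)])
    h = config.pole_half_separation * rbar
    shp = Polygon(poly)
    shrunk = False
    while h > 1e-9 * rbar and not (shp.contains(Point(centroid + h * u))
                                   and shp.contains(Point(centroid - h * u))):
        h *= 0.5
        shrunk = True
    return centroid, h * u, shrunk


def spindle_torque(poly: np.ndarray, phi: float, config: MincConfig | None = None,
                   ) -> float:
    """Net z-torque on a spindle at orientation ``phi`` (degrees).

    Poles sit at +-(pole_half_separation x mean centroid-vertex distance)
    from the area centroid along phi; each pole casts ``n_rays`` uniformly
    spaced astral rays over its outward half-fan, and each ray pulls on
    the pole with force l**beta directed along the ray.  Torque is the
    mean over rays, summed over poles, of the z-component of
    (pole - centroid) x force.  The two poles are identical, so the
    profile is 180-degree periodic; for mirror-symmetric cells it is odd
    about the symmetry axes.
    """
    config = config or MincConfig()
    return _torque(np.asarray(poly, float), phi, config)[0]


def _torque(poly: np.ndarray, phi: float, config: MincConfig) -> tuple[float, bool]:
    phi_rad = np.radians(phi)
    centroid, arm, shrunk = _pole_positions(poly, phi_rad, config)
    # outward half-fan offsets, uniform, symmetric about the pole axis
    offs = np.pi * (np.arange(config.n_rays) + 0.5) / config.n_rays - np.pi / 2
    torque = 0.0
    for sign in (+1.0, -1.0):
        pole = centroid + sign * arm
        base = phi_rad if sign > 0 else phi_rad + np.pi
        ang = base + offs
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
        lengths = ray_lengths(poly, pole, dirs)
        forces = (lengths**config.beta)[:, None] * dirs
        lever = sign * arm
        torque += float(np.sum(lever[0] * forces[:, 1] - lever[1] * forces[:, 0]))
    return torque / config.n_rays, shrunk


def _torque_scale(poly, config):
    """Degeneracy scale: mean over rays of l**(beta+1) from the centroid."""
    centroid = _area_centroid(poly)
    angles = 2 * np.pi * np.arange(config.n_rays) / config.n_rays
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    lengths = ray_lengths(poly, centroid, dirs)
    return float(np.mean(lengths ** (config.beta + 1)))


def predict_division_axis(poly: np.ndarray, config: MincConfig | None = None,
                          tie_axis: float | None = None) -> MincPrediction:
    """Predicted division axis: the stable torque-free spindle orientation.

    The torque profile is scanned over [0, 180) at ``angle_grid`` degrees.
    Stable equilibria are sign changes with restoring slope (torque
    positive before, negative after, so a perturbed spindle rotates
    back); each is refined by bisection.  Among multiple stable zeros the
    one minimizing the rotational potential -integral(torque) wins.

    A flat profile, or symmetry-tied potentials among distinct stable
    axes, is degenerate; a tie is instead broken toward ``tie_axis``
    (axial degrees) when one is supplied.
    """
    config = config or MincConfig()
    poly = np.asarray(poly, float)
    phis = np.arange(0.0, 180.0, config.angle_grid)
    scanned = [_torque(poly, p, config) for p in phis]
    tq = np.array([t for t, _ in scanned])
    shrunk = any(s for _, s in scanned)
    scale = _torque_scale(poly, config)
    profile = np.column_stack([phis, tq])
    if np.abs(tq).max() < config.degeneracy_rtol * scale:
        return MincPrediction(theta_minc=0.0, torque_profile=profile,
                              degenerate=True, pole_shrunk=shrunk)
    # rotational potential on the periodic grid (trapezoid, wraps at 180)
    dphi = np.radians(config.angle_grid)
    mid = 0.5 * (tq + np.roll(tq, -1)) * dphi
    pot = -np.concatenate([[0.0], np.cumsum(mid[:-1])])
    candidates = []
    n = len(phis)
    for k in range(n):
        t1, t2 = tq[k], tq[(k + 1) % n]
        if t1 > 0 and t2 <= 0:  # restoring crossing
            root = _bisect_root(poly, phis[k], phis[k] + config.angle_grid,
                                config)
            # potential at the root itself (trapezoid over the partial step)
            v = float(pot[k]) - 0.5 * t1 * np.radians(root - phis[k])
            candidates.append((v, float(np.mod(root, 180.0))))
    if not candidates:
        return MincPrediction(theta_minc=0.0, torque_profile=profile,
                              degenerate=True, pole_shrunk=shrunk)
    vmin = min(c[0] for c in candidates)
    # symmetry-related minima agree up to the trapezoid quadrature error,
    # well below 1e-3 of the potential range at the default grid
    tie_tol = 1e-3 * (float(pot.max() - pot.min()) + 1e-300)
    tied = [c for c in candidates if c[0] - vmin <= tie_tol]
    if len(tied) > 1:
        # distinct axes with symmetry-tied potentials
        from .shape import fold_axial_difference
        axes = [c[1] for c in tied]
        spread = max(fold_axial_difference(a, axes[0]) for a in axes)
        if spread > 2.0 * config.angle_grid:
            if tie_axis is not None:
                best = min(tied, key=lambda c: fold_axial_difference(c[1], tie_axis))
                return MincPrediction(theta_minc=best[1], torque_profile=profile,
                                      degenerate=False, pole_shrunk=shrunk,
                                      tie_broken=True)
            return MincPrediction(theta_minc=0.0, torque_profile=profile,
                                  degenerate=True, pole_shrunk=shrunk)
    best = min(candidates, key=lambda c: c[0])
    return MincPrediction(theta_minc=best[1], torque_profile=profile,
                          degenerate=False, pole_shrunk=shrunk)


def _bisect_root(poly, lo, hi, config, iters=40):
    flo = spindle_torque(poly, lo, config)
    fhi = spindle_torque(poly, hi, config)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = spindle_torque(poly, mid, config)
        if fm == 0:
            return mid
        if (flo > 0) == (fm > 0):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)
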