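"""Synthetic tissues, fixtures and division events.

Everything the analysis pipeline consumes can be generated here with a
seed: deterministic fixture polygons, lattice and Voronoi tissues, and
division events whose axial angles concentrate around a chosen shape
axis with a tunable von Mises concentration (kappa = 0 is uniform,
kappa -> infinity is perfect alignment).  Axial angles are modelled on
the doubled circle (von Mises on 2 theta), the standard treatment for
orientation (as opposed to direction) data.

Scenario bundles package a tissue, its division events and a manifest of
the qualitative conclusions the pipeline is expected to reach, emulating
the structure of stretched/unstretched explant experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import Tissue
from .shape import DivisionEvent, characterize_tissue
from .simulate import _periodic_voronoi, apply_uniaxial_stretch

KAPPA_CAP = 1e6

FIXTURE_KINDS = ("unit_square", "rectangle", "regular_ngon", "hex_lattice",
                 "perturbed_lattice", "displaced_tcj_hexagon", "brick_wall")


@dataclass
class DivisionGeneratorConfig:
    """Controls the synthetic division generator.

    ``division_fraction_per_hour`` is the percentage of cells entering
    mitosis per hour (explant-like defaults: 3.22 unstretched, 6.47
    stretched); ``kappa`` is the axial von Mises concentration of the
    division angle around the reference axis.
    """

    axis_source: str = "junction"   # junction | area | perimeter | stretch | fixed_angle
    kappa: float = 0.0
    division_fraction_per_hour: float = 3.22
    duration: float = 2.0           # hours
    seed: int = 0
    fixed_angle: float = 0.0        # used when axis_source == "fixed_angle"
    neb_profile: str = "uniform"    # uniform | two_phase
    rate_early: float = 8.1         # %/h before the break (two_phase profile)
    rate_late: float = 4.35         # %/h after the break
    break_min: float = 50.0
    interior_only: bool = True      # skip border cells of bounded tissues

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0 <= self.division_fraction_per_hour <= 100:
            raise ValueError("division fraction must be a percentage")
        if self.axis_source not in ("junction", "area", "perimeter",
                                    "stretch", "fixed_angle"):
            raise ValueError(f"unknown axis_source {self.axis_source!r}")


@dataclass
class ScenarioBundle:
    name: str
    seed: int
    tissue: Tissue
    divisions: list[DivisionEvent]
    manifest: dict
    extra: dict = field(default_factory=dict)


# ------------------------------------------------------------------ fixtures

def make_fixture(kind: str, **kwargs) -> Tissue:
    """Deterministic fixture geometries.

    Kinds: ``unit_square``; ``rectangle(a, b)``; ``regular_ngon(n, area)``;
    ``hex_lattice(nx, ny)`` (periodic honeycomb, unit cell area);
    ``perturbed_lattice(nx, ny, sigma, seed)``;
    ``displaced_tcj_hexagon`` (a round 12-gon whose six annotated TCJs
    cluster around one axis: circular by area and perimeter, clearly
    elongated by junctions); ``brick_wall(nx, ny, aspect)`` (running-bond
    rectangles whose area axis is horizontal but whose TCJ axis is
    vertical for 1 < aspect < sqrt(3/2)).

    Single-polygon fixtures annotate every vertex as a TCJ unless stated
    otherwise.
    """
    try:
        builder = _FIXTURES[kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"expected one of {FIXTURE_KINDS}") from None
    return builder(**kwargs)


def _single_cell(poly: np.ndarray, degree: np.ndarray | None = None) -> Tissue:
    poly = np.asarray(poly, float)
    if degree is None:
        degree = np.full(len(poly), 3, dtype=int)
    return Tissue(vertices=poly, cells=[np.arange(len(poly))],
                  junction_degree=degree)


def _unit_square() -> Tissue:
    return _single_cell([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _rectangle(a: float = 2.0, b: float = 1.0) -> Tissue:
    if a <= 0 or b <= 0:
        raise ValueError("rectangle sides must be positive")
    return _single_cell([[-a / 2, -b / 2], [a / 2, -b / 2],
                         [a / 2, b / 2], [-a / 2, b / 2]])


def regular_ngon(n: int = 6, area: float = 1.0) -> np.ndarray:
    """Vertices of a regular n-gon with the given area, centred at 0."""
    if n < 3:
        raise ValueError("need n >= 3")
    if area <= 0:
        raise ValueError("area must be positive")
    r = np.sqrt(2.0 * area / (n * np.sin(2 * np.pi / n)))
    ang = 2 * np.pi * np.arange(n) / n
    return r * np.column_stack([np.cos(ang), np.sin(ang)])


def _regular_ngon_tissue(n: int = 6, area: float = 1.0) -> Tissue:
    return _single_cell(regular_ngon(n, area))


def _triangular_points(nx: int, ny: int, spacing: float):
    if ny % 2:
        raise ValueError("ny must be even for a periodic triangular lattice")
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ii + 0.5 * (jj % 2)) * spacing
    y = jj * spacing * np.sqrt(3) / 2
    return np.column_stack([x.ravel(), y.ravel()]), nx * spacing, ny * spacing * np.sqrt(3) / 2


def _hex_lattice(nx: int = 4, ny: int = 4) -> Tissue:
    spacing = np.sqrt(2.0 / np.sqrt(3.0))  # unit cell area
    pts, lx, ly = _triangular_points(nx, ny, spacing)
    return _voronoi_rect(pts, lx, ly)


def _perturbed_lattice(nx: int = 6, ny: int = 6, sigma: float = 0.15,
                       seed: int = 0) -> Tissue:
    spacing = np.sqrt(2.0 / np.sqrt(3.0))
    rng = np.random.default_rng(seed)
    pts, lx, ly = _triangular_points(nx, ny, spacing)
    pts = np.mod(pts + rng.normal(scale=sigma * spacing, size=pts.shape),
                 [lx, ly])
    return _voronoi_rect(pts, lx, ly)


def _voronoi_rect(points: np.ndarray, lx: float, ly: float) -> Tissue:
    return _periodic_voronoi(np.mod(points, [lx, ly]), (lx, ly))


def _displaced_tcj_hexagon() -> Tissue:
    """A circular cell (regular 12-gon) whose six TCJs cluster around the
    30-degree axis: C_A and C_P are 1, C_J is far below 1."""
    poly = regular_ngon(12, area=1.0)
    degree = np.full(12, 2, dtype=int)
    # vertices at 0, 30, 60, 180, 210, 240 degrees are TCJs
    degree[[0, 1, 2, 6, 7, 8]] = 3
    return _single_cell(poly, degree)


def _brick_wall(nx: int = 10, ny: int = 8, aspect: float = 1.1,
                height: float = 1.0) -> Tissue:
    """Bounded running-bond brick tissue.

    Bricks are ``aspect * height`` wide; every interior vertex (corner or
    edge midpoint) touches three bricks.  For 1 < aspect < sqrt(3/2) the
    area-shape axis is horizontal (0 deg) while the TCJ axis is vertical
    (90 deg), decoupling the two characterizations.
    """
    w = aspect * height
    vmap: dict[tuple[int, int], int] = {}
    verts: list[tuple[float, float]] = []

    def vid(xhalf: int, j: int) -> int:
        key = (xhalf, j)
        if key not in vmap:
            vmap[key] = len(verts)
            verts.append((xhalf * w / 2.0, j * height))
        return vmap[key]

    cells = []
    for j in range(ny):
        off = j % 2  # row offset in half-widths
        for i in range(nx):
            x0 = 2 * i + off
            loop = [vid(x0, j), vid(x0 + 1, j), vid(x0 + 2, j),
                    vid(x0 + 2, j + 1), vid(x0 + 1, j + 1), vid(x0, j + 1)]
            cells.append(np.asarray(loop, dtype=int))
    return Tissue(vertices=np.asarray(verts, float),
                  cells=cells)


_FIXTURES = {
    "unit_square": _unit_square,
    "rectangle": _rectangle,
    "regular_ngon": _regular_ngon_tissue,
    "hex_lattice": _hex_lattice,
    "perturbed_lattice": _perturbed_lattice,
    "displaced_tcj_hexagon": _displaced_tcj_hexagon,
    "brick_wall": _brick_wall,
}


# ------------------------------------------------------------------ divisions

def sample_axial_angles(reference_deg, kappa: float, rng) -> np.ndarray:
    """Axial angles concentrated around reference axes: von Mises on the
    doubled angle, folded to [0, 180)."""
    kappa = min(kappa, KAPPA_CAP)
    ref = np.asarray(reference_deg, float)
    noise2 = rng.vonmises(0.0, kappa, size=ref.shape)  # on 2*theta
    return np.mod(ref + np.degrees(noise2) / 2.0, 180.0)


def sample_divisions(tissue: Tissue, config: DivisionGeneratorConfig,
                     shapes: pd.DataFrame | None = None) -> list[DivisionEvent]:
    """Draw division events on a tissue.

    Dividing cells are Bernoulli draws at
    ``division_fraction_per_hour * duration``; each division angle is an
    axial von Mises draw around the cell's reference axis, and NEB times
    follow the configured temporal profile.  Cells with a degenerate
    reference axis (no defined orientation) never divide here.
    """
    rng = np.random.default_rng(config.seed)
    if shapes is None:
        shapes = characterize_tissue(tissue)
    shapes = shapes.set_index("cell_id")
    p = config.division_fraction_per_hour / 100.0 * config.duration
    col = {"junction": ("theta_J", "degenerate_J"),
           "area": ("theta_A", "degenerate_A"),
           "perimeter": ("theta_P", "degenerate_P")}
    events: list[DivisionEvent] = []
    for cell_id in range(tissue.n_cells):
        s = shapes.loc[cell_id]
        if config.interior_only and bool(s.boundary):
            continue
        if config.axis_source in col:
            tcol, dcol = col[config.axis_source]
            if bool(s[dcol]):
                continue
            ref = float(s[tcol])
        elif config.axis_source == "stretch":
            ref = 0.0
        else:
            ref = config.fixed_angle
        if rng.random() >= p:
            continue
        theta = float(sample_axial_angles(ref, config.kappa, rng))
        poly = tissue.cell_polygon(cell_id)
        centroid = poly.mean(axis=0)
        eps = 0.15 * np.sqrt(float(s.area))
        d = eps * np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
        events.append(DivisionEvent(
            cell_id=cell_id, t_neb=float(_neb_time(rng, config)),
            daughter_a=tuple(centroid + d), daughter_b=tuple(centroid - d)))
    return events


def _neb_time(rng, config: DivisionGeneratorConfig) -> float:
    total_min = config.duration * 60.0
    if config.neb_profile == "uniform":
        return rng.uniform(0.0, total_min)
    if config.neb_profile == "two_phase":
        tb = min(config.break_min, total_min)
        w_early = config.rate_early * tb
        w_late = config.rate_late * (total_min - tb)
        if rng.random() < w_early / (w_early + w_late):
            return rng.uniform(0.0, tb)
        return rng.uniform(tb, total_min)
    raise ValueError(f"unknown neb_profile {config.neb_profile!r}")


def divisions_to_frame(events: list[DivisionEvent]) -> pd.DataFrame:
    rows = [{"cell_id": ev.cell_id, "t_neb_min": ev.t_neb,
             "ax": ev.daughter_a[0], "ay": ev.daughter_a[1],
             "bx": ev.daughter_b[0], "by": ev.daughter_b[1],
             "theta_d": ev.theta_d} for ev in events]
    return pd.DataFrame(rows, columns=["cell_id", "t_neb_min", "ax", "ay",
                                       "bx", "by", "theta_d"])


def divisions_from_frame(df: pd.DataFrame) -> list[DivisionEvent]:
    return [DivisionEvent(cell_id=int(r.cell_id), t_neb=float(r.t_neb_min),
                          daughter_a=(float(r.ax), float(r.ay)),
                          daughter_b=(float(r.bx), float(r.by)))
            for r in df.itertuples()]


# ------------------------------------------------------------------ scenarios

SCENARIOS = ("unstretched_control", "stretched_control", "tcj_only_signal",
             "myosin_like_rate_shift")


def end_to_end_scenario(name: str, seed: int = 0) -> ScenarioBundle:
    """Packaged tissue + divisions + manifest of expected conclusions."""
    if name == "unstretched_control":
        tissue = make_fixture("perturbed_lattice", nx=18, ny=18, sigma=0.18,
                              seed=seed)
        cfg = DivisionGeneratorConfig(axis_source="junction", kappa=0.0,
                                      division_fraction_per_hour=3.22,
                                      duration=2.0, seed=seed + 1)
        manifest = {"stretched": False,
                    "division_angles_uniform": True,
                    "expect_ks_uniform_significant": False}
        return ScenarioBundle(name, seed, tissue, sample_divisions(tissue, cfg),
                              manifest)
    if name == "stretched_control":
        base = make_fixture("perturbed_lattice", nx=18, ny=18, sigma=0.18,
                            seed=seed)
        tissue = apply_uniaxial_stretch(base, 0.13)
        cfg = DivisionGeneratorConfig(axis_source="junction", kappa=2.0,
                                      division_fraction_per_hour=6.47,
                                      duration=2.0, seed=seed + 1,
                                      neb_profile="two_phase")
        manifest = {"stretched": True,
                    "expect_theta_j_near_stretch_axis": True,
                    "expect_ks_uniform_significant": True,
                    "expect_junction_alignment_significant": True}
        return ScenarioBundle(name, seed, tissue, sample_divisions(tissue, cfg),
                              manifest)
    if name == "tcj_only_signal":
        tissue = make_fixture("brick_wall", nx=20, ny=16, aspect=1.1)
        cfg = DivisionGeneratorConfig(axis_source="junction", kappa=6.0,
                                      division_fraction_per_hour=8.0,
                                      duration=2.0, seed=seed + 1)
        manifest = {"stretched": False,
                    "expect_junction_alignment_significant": True,
                    "expect_area_alignment_significant_on_AJ15": False,
                    "all_cells_satisfy_AJ15": True}
        return ScenarioBundle(name, seed, tissue, sample_divisions(tissue, cfg),
                              manifest)
    if name == "myosin_like_rate_shift":
        tissue = make_fixture("perturbed_lattice", nx=18, ny=18, sigma=0.18,
                              seed=seed)
        low = DivisionGeneratorConfig(axis_source="junction", kappa=0.0,
                                      division_fraction_per_hour=0.4,
                                      duration=2.0, seed=seed + 1)
        high = DivisionGeneratorConfig(axis_source="junction", kappa=0.0,
                                       division_fraction_per_hour=3.0,
                                       duration=2.0, seed=seed + 2)
        manifest = {"stretched": True,
                    "expect_rate_elevated_when_stretched": True,
                    "dividing_cells_area_decoupled": True}
        return ScenarioBundle(name, seed, tissue,
                              sample_divisions(tissue, high), manifest,
                              extra={"divisions_unstretched":
                                     sample_divisions(tissue, low)})
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
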