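"""Vertex-model tissue simulator: generation, relaxation, stretch.

Tissues are periodic polygonal meshes whose vertices move to minimize the
dimensionless vertex-model energy

    U = sum_cells [ 1/2 (A - 1)^2 + 1/2 Gamma L^2 + 1/2 Lambda L ],

(the per-edge line tension Lambda sum over edges written per cell, hence
the 1/2).  Relaxation is quasi-Newton (L-BFGS) descent on analytic
forces; with ``box_mode="relax"`` the 2x2 periodic box matrix (including
its shear component) is a degree of freedom, so a relaxed tissue sits at
zero global stress.  Edges shorter than a threshold undergo T1
neighbour exchanges, after which relaxation resumes.

A uniaxial stretch is the area-preserving affine map
x -> (1 + f) x, y -> y / (1 + f) applied to vertices and box; subsequent
relaxation holds the box fixed (modelling a substrate-held tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Voronoi

from .mesh import GeometryError, Tissue, signed_area
from .stress import MechParams

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_cells: int = 50
    seed: int = 0
    params: MechParams = field(default_factory=MechParams)
    force_tol: float = 1e-6
    t1_threshold: float = 0.02       # in units of sqrt(mean cell area)
    stretch_fraction: float = 0.13
    box_mode: str = "relax"          # "relax" or "fixed"
    max_iter: int = 50000
    t1_rest_factor: float = 1.5      # post-swap edge length / t1_threshold
    max_t1_passes: int = 20

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.force_tol <= 0:
            raise ValueError("force_tol must be positive")
        if self.stretch_fraction <= -1:
            raise ValueError("stretch fraction must exceed -1")
        if self.box_mode not in ("relax", "fixed"):
            raise ValueError(f"unknown box_mode {self.box_mode!r}")


@dataclass
class RelaxResult:
    tissue: Tissue
    energy: float
    energy_trajectory: np.ndarray
    max_force: float
    converged: bool
    n_t1: int = 0


# ------------------------------------------------------------ random tissues

def generate_random_tissue(n_cells: int, seed: int = 0,
                           box_length: float | None = None) -> Tissue:
    """Periodic Voronoi tessellation of uniformly sampled seed points.

    The square box side defaults to sqrt(n_cells), so the mean cell area
    is 1 (the natural units of the vertex-model energy).  Deterministic
    given ``seed``; degenerate point configurations are retried with an
    incremented sub-seed.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    side = float(np.sqrt(n_cells)) if box_length is None else float(box_length)
    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        pts = rng.random((n_cells, 2)) * side
        try:
            tissue = _periodic_voronoi(pts, (side, side))
            tissue.validate()
            return tissue
        except (GeometryError, KeyError, AssertionError) as exc:  # pragma: no cover
            logger.warning("degenerate Voronoi seed configuration "
                           "(seed=%s, attempt=%d): %s; retrying", seed, attempt, exc)
    raise RuntimeError(f"could not build a valid Voronoi tissue for seed {seed}")


def _periodic_voronoi(points: np.ndarray, box_lengths) -> Tissue:
    """Voronoi tessellation of points in a periodic rectangular box."""
    n = len(points)
    lx, ly = float(box_lengths[0]), float(box_lengths[1])
    shifts = np.array([[i * lx, j * ly] for i in (-1, 0, 1) for j in (-1, 0, 1)])
    central = int(np.where((shifts == 0).all(axis=1))[0][0])
    tiled = (points[None, :, :] + shifts[:, None, :]).reshape(-1, 2)
    vor = Voronoi(tiled)
    vmap: dict[tuple[int, int], int] = {}
    verts: list[np.ndarray] = []
    cells = []
    offsets = []
    for k in range(central * n, central * n + n):
        region = vor.regions[vor.point_region[k]]
        assert -1 not in region and len(region) >= 3, "unbounded Voronoi region"
        loop = []
        offs = []
        for vi in region:
            v = vor.vertices[vi]
            w = np.mod(v, [lx, ly])
            w = np.where(w / [lx, ly] > 1 - 1e-12, 0.0, w)  # snap box edge to 0
            key = (int(round(w[0] / lx * 1e9)) % int(1e9),
                   int(round(w[1] / ly * 1e9)) % int(1e9))
            if key not in vmap:
                vmap[key] = len(verts)
                verts.append(w)
            loop.append(vmap[key])
            offs.append(np.round((v - verts[vmap[key]]) / [lx, ly]))
        cells.append(np.asarray(loop, dtype=int))
        offsets.append(np.asarray(offs, dtype=float))
    tissue = Tissue(vertices=np.asarray(verts), cells=cells,
                    box=np.diag([lx, ly]), offsets=offsets)
    _orient_ccw(tissue)
    return tissue


def _orient_ccw(tissue: Tissue) -> None:
    flips = [i for i in range(tissue.n_cells)
             if signed_area(tissue.cell_polygon(i)) < 0]
    for i in flips:
        tissue.cells[i] = tissue.cells[i][::-1]
        if tissue.offsets is not None:
            tissue.offsets[i] = tissue.offsets[i][::-1]
    if flips:
        tissue._offsets = None


# -------------------------------------------------------- energy and forces

def _cell_energy_grad(r: np.ndarray, lam: float, gamma: float):
    """Energy and dU/dr for one unwrapped CCW cell polygon."""
    rn = np.roll(r, -1, axis=0)
    rp = np.roll(r, 1, axis=0)
    e = rn - r
    el = np.linalg.norm(e, axis=1)
    area = 0.5 * np.sum(r[:, 0] * rn[:, 1] - rn[:, 0] * r[:, 1])
    perim = el.sum()
    u = 0.5 * (area - 1.0) ** 2 + 0.5 * gamma * perim**2 + 0.5 * lam * perim
    d_area = 0.5 * np.column_stack([rn[:, 1] - rp[:, 1], rp[:, 0] - rn[:, 0]])
    ehat = e / el[:, None]
    d_perim = np.roll(ehat, 1, axis=0) - ehat
    tension = gamma * perim + 0.5 * lam
    return u, (area - 1.0) * d_area + tension * d_perim


def tissue_energy(tissue: Tissue, params: MechParams) -> float:
    lam, gamma = params.lam, params.gamma
    return float(sum(_cell_energy_grad(tissue.cell_polygon(i), lam, gamma)[0]
                     for i in range(tissue.n_cells)))


def vertex_forces(tissue: Tissue, params: MechParams) -> np.ndarray:
    """Analytic force -dU/dr on every vertex, (N, 2)."""
    g = np.zeros_like(tissue.vertices)
    for i, loop in enumerate(tissue.cells):
        _, gc = _cell_energy_grad(tissue.cell_polygon(i), params.lam, params.gamma)
        np.add.at(g, loop, gc)
    return -g


def _pack(frac: np.ndarray, box: np.ndarray, relax_box: bool) -> np.ndarray:
    if relax_box:
        return np.concatenate([frac.ravel(), [box[0, 0], box[0, 1], box[1, 1]]])
    return frac.ravel()


def _unpack(x: np.ndarray, nv: int, box0: np.ndarray, relax_box: bool):
    frac = x[: 2 * nv].reshape(nv, 2)
    if relax_box:
        box = np.array([[x[-3], x[-2]], [0.0, x[-1]]])
    else:
        box = box0
    return frac, box


def _energy_grad_packed(x, cells, offsets, nv, box0, relax_box, lam, gamma):
    frac, box = _unpack(x, nv, box0, relax_box)
    gs = np.zeros((nv, 2))
    g_box = np.zeros((2, 2))
    total = 0.0
    for loop, offs in zip(cells, offsets):
        u = frac[loop] + offs
        r = u @ box
        uc, gc = _cell_energy_grad(r, lam, gamma)
        total += uc
        np.add.at(gs, loop, gc @ box.T)
        if relax_box:
            g_box += u.T @ gc
    if relax_box:
        grad = np.concatenate([gs.ravel(), [g_box[0, 0], g_box[0, 1], g_box[1, 1]]])
    else:
        grad = gs.ravel()
    return total, grad


def relax(tissue: Tissue, config: SimulationConfig) -> RelaxResult:
    """Minimize the vertex-model energy over vertex positions (and box).

    T1 swaps are applied to edges shorter than
    ``config.t1_threshold * sqrt(mean cell area)`` between relaxation
    passes.  Convergence is declared when the maximum vertex force norm
    drops below ``config.force_tol``; non-convergence returns the partial
    result with ``converged=False``.
    """
    if tissue.box is None:
        raise GeometryError("relaxation requires a periodic tissue")
    work = tissue.copy()
    params = config.params
    relax_box = config.box_mode == "relax"
    traj: list[float] = []
    n_t1 = 0
    for t1_pass in range(config.max_t1_passes + 1):
        work = _relax_vertices(work, config, relax_box, traj)
        short = _shortest_swappable_edge(work, config)
        if short is None or t1_pass == config.max_t1_passes:
            break
        _t1_swap(work, *short, rest_length=config.t1_rest_factor
                 * config.t1_threshold * np.sqrt(work.box_area() / work.n_cells))
        n_t1 += 1
        logger.info("T1 swap %d applied to edge %s", n_t1, short[:2])
    forces = vertex_forces(work, params)
    max_force = float(np.linalg.norm(forces, axis=1).max())
    return RelaxResult(tissue=work, energy=tissue_energy(work, params),
                       energy_trajectory=np.asarray(traj),
                       max_force=max_force,
                       converged=max_force < config.force_tol, n_t1=n_t1)


def _relax_vertices(tissue: Tissue, config: SimulationConfig,
                    relax_box: bool, traj: list[float]) -> Tissue:
    nv = tissue.n_vertices
    frac = tissue.fractional()
    offsets = tissue.cell_offsets()
    box0 = tissue.box
    args = (tissue.cells, offsets, nv, box0, relax_box,
            config.params.lam, config.params.gamma)
    x0 = _pack(frac, box0, relax_box)

    def cb(xk):
        traj.append(_energy_grad_packed(xk, *args)[0])

    res = minimize(_energy_grad_packed, x0, args=args, jac=True,
                   method="L-BFGS-B", callback=cb,
                   options=dict(maxiter=config.max_iter, maxfun=4 * config.max_iter,
                                ftol=0.0, gtol=min(1e-10, 0.1 * config.force_tol)))
    frac, box = _unpack(res.x, nv, box0, relax_box)
    # re-wrap into the box, shifting per-occurrence offsets to compensate
    shift = np.floor(frac)
    new_offsets = [o + shift[loop] for o, loop in zip(offsets, tissue.cells)]
    out = Tissue(vertices=(frac - shift) @ box,
                 cells=[c.copy() for c in tissue.cells], box=box,
                 offsets=new_offsets)
    return out


# ------------------------------------------------------------------ T1 swaps

def _shortest_swappable_edge(tissue: Tissue, config: SimulationConfig):
    """Shortest interior edge below threshold, as (a, b, cells) or None."""
    thresh = config.t1_threshold * np.sqrt(tissue.box_area() / tissue.n_cells)
    frac = tissue.fractional()
    deg = tissue.junction_degrees()
    best = None
    for (a, b, off), cs in tissue.edge_map().items():
        if len(cs) != 2:
            continue
        d = frac[b] + np.asarray(off) - frac[a]
        length = float(np.linalg.norm(d @ tissue.box))
        if length < thresh and (best is None or length < best[0]):
            # both endpoints must be 3-valent for a clean neighbour exchange
            if deg[a] == 3 and deg[b] == 3:
                best = (length, a, b, cs)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _t1_swap(tissue: Tissue, a: int, b: int, edge_cells: list[int],
             rest_length: float) -> None:
    """Neighbour exchange on interior edge (a, b), in place.

    The two cells sharing the edge each lose one endpoint; the two cells
    previously meeting the edge only at a or only at b gain the rotated
    edge.  New endpoint positions sit on the perpendicular bisector of the
    old edge at separation ``rest_length``.
    """
    cells_with_a = [i for i, c in enumerate(tissue.cells) if a in c]
    cells_with_b = [i for i, c in enumerate(tissue.cells) if b in c]
    c1 = next(i for i in edge_cells if _has_directed_edge(tissue.cells[i], a, b))
    c2 = next(i for i in edge_cells if _has_directed_edge(tissue.cells[i], b, a))
    c3 = next(i for i in cells_with_a if i not in edge_cells)
    c4 = next(i for i in cells_with_b if i not in edge_cells)

    # geometry in c1's unwrapped frame
    poly1 = tissue.cell_polygon(c1)
    loop1 = list(tissue.cells[c1])
    ra = poly1[loop1.index(a)]
    rb = poly1[loop1.index(b)]
    v = rb - ra
    nhat = np.array([-v[1], v[0]]) / np.linalg.norm(v)  # left normal: points into c1
    m = 0.5 * (ra + rb)
    new_a = m + 0.5 * rest_length * nhat   # endpoint retained by c1
    new_b = m - 0.5 * rest_length * nhat

    # topology: c1 keeps a, c2 keeps b, c3/c4 gain the edge.  In c3 the
    # flank edge preceding a decides the insertion order: the new vertex
    # adjacent to that flank is the one kept by the cell sharing it
    # (c1 keeps a, c2 keeps b).  Decisions precede any mutation.
    first3 = a if _flank_cell(tissue, c3, a, before=True) == c1 else b
    first4 = a if _flank_cell(tissue, c4, b, before=True) == c1 else b
    tissue.cells[c1] = _drop_vertex(tissue.cells[c1], b)
    tissue.cells[c2] = _drop_vertex(tissue.cells[c2], a)
    tissue.cells[c3] = _insert_pair(tissue.cells[c3], a, b, first=first3)
    tissue.cells[c4] = _insert_pair(tissue.cells[c4], b, a, first=first4)

    inv = np.linalg.inv(tissue.box)
    tissue.vertices[a] = np.mod(new_a @ inv, 1.0) @ tissue.box
    tissue.vertices[b] = np.mod(new_b @ inv, 1.0) @ tissue.box
    # loops changed: fall back to minimum-image unwrapping
    tissue.offsets = None
    tissue._offsets = None


def _has_directed_edge(loop: np.ndarray, a: int, b: int) -> bool:
    loop = list(loop)
    k = loop.index(a)
    return loop[(k + 1) % len(loop)] == b


def _drop_vertex(loop: np.ndarray, v: int) -> np.ndarray:
    return np.asarray([x for x in loop if x != v], dtype=int)


def _insert_pair(loop: np.ndarray, at: int, other: int, first: int) -> np.ndarray:
    out = []
    pair = [first, other if first == at else at]
    for x in loop:
        if x == at:
            out.extend(pair)
        else:
            out.append(x)
    return np.asarray(out, dtype=int)


def _flank_cell(tissue: Tissue, cell: int, v: int, before: bool) -> int:
    """Cell sharing the edge that precedes (or follows) vertex v in the
    given cell's loop."""
    loop = list(tissue.cells[cell])
    k = loop.index(v)
    nb = loop[(k - 1) % len(loop)] if before else loop[(k + 1) % len(loop)]
    for i, other in enumerate(tissue.cells):
        if i == cell:
            continue
        ol = list(other)
        if v in ol and nb in ol:
            j = ol.index(v)
            if ol[(j + 1) % len(ol)] == nb or ol[(j - 1) % len(ol)] == nb:
                return i
    raise GeometryError(f"no cell shares edge ({v}, {nb}) with cell {cell}")


# ------------------------------------------------------------------- stretch

def apply_uniaxial_stretch(tissue: Tissue, fraction: float) -> Tissue:
    """Area-preserving uniaxial stretch along x: x -> (1+f) x, y -> y/(1+f).

    Applied affinely to vertices and box; the box area is conserved.
    """
    if tissue.box is None:
        raise GeometryError("stretch requires a periodic tissue")
    if fraction <= -1:
        raise ValueError("stretch fraction must exceed -1")
    s = np.diag([1.0 + fraction, 1.0 / (1.0 + fraction)])
    out = tissue.copy()
    out.vertices = out.vertices @ s
    out.box = out.box @ s
    return out


# ------------------------------------------------------------ full protocol

def simulate_stretch_experiment(config: SimulationConfig):
    """Generate, relax at zero global stress, stretch, re-relax (fixed box).

    Returns ``(pre, post)`` :class:`RelaxResult` pairs reproducing the
    simulated-tissue stretch experiment.
    """
    tissue = generate_random_tissue(config.n_cells, config.seed)
    pre = relax(tissue, config)
    stretched = apply_uniaxial_stretch(pre.tissue, config.stretch_fraction)
    fixed_cfg = SimulationConfig(**{**config.__dict__, "box_mode": "fixed"})
    post = relax(stretched, fixed_cfg)
    return pre, post
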