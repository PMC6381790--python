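import numpy as np
import pytest

import epimech as em
from epimech.synth import regular_ngon


@pytest.fixture(scope="session")
def unit_hexagon() -> np.ndarray:
    """Regular hexagon of unit area, centred at the origin."""
    return regular_ngon(6, 1.0)


@pytest.fixture(scope="session")
def rect_2x1() -> np.ndarray:
    return np.array([[-1.0, -0.5], [1.0, -0.5], [1.0, 0.5], [-1.0, 0.5]])


@pytest.fixture(scope="session")
def relaxed_tissue():
    """A small random periodic tissue relaxed at zero global stress."""
    cfg = em.SimulationConfig(n_cells=24, seed=7)
    tissue = em.generate_random_tissue(24, seed=7)
    res = em.relax(tissue, cfg)
    assert res.converged
    return res.tissue


def random_convex_polygon(rng, n=8, scale=1.0):
    """Random star-shaped polygon: angularly well-separated points on a
    noisy circle (always simple and counter-clockwise)."""
    ang = (np.arange(n) + rng.uniform(0.2, 0.8, n)) * 2 * np.pi / n
    r = scale * rng.uniform(0.6, 1.4, n)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])
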