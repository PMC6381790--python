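import numpy as np
import pandas as pd
import pytest

from epimech.shape import DivisionEvent, fold_axial_difference
from epimech.stats import (build_alignment_table, division_rate, fit_neb_phases,
                           ks_two_sample, ks_vs_uniform, mannwhitney_vs_uniform,
                           spearman_correlation)


def make_shapes(rows):
    defaults = dict(theta_A=0.0, theta_P=0.0, theta_J=0.0, C_A=0.5, C_P=0.5,
                    C_J=0.5, degenerate_A=False, degenerate_P=False,
                    degenerate_J=False, boundary=False)
    return pd.DataFrame([{**defaults, "cell_id": i, **r}
                         for i, r in enumerate(rows)])


def event(cell_id, theta_d):
    r = np.radians(theta_d)
    return DivisionEvent(cell_id=cell_id, t_neb=0.0, daughter_a=(0.0, 0.0),
                         daughter_b=(np.cos(r), np.sin(r)))


# ------------------------------------------------------------ alignment table

def test_alignment_diff_and_filters_basic():
    shapes = make_shapes([dict(theta_J=170.0, C_A=0.5)])
    table = build_alignment_table([event(0, 10.0)], shapes)
    junc = table[table.method == "junction"].iloc[0]
    assert junc["diff"] == pytest.approx(20.0)
    assert not junc.flt_round_A   # C_A = 0.5 fails the round filter
    assert not junc.flt_AJ15      # |theta_A - theta_J| folds to 10 < 15


def test_alignment_filter_semantics():
    shapes = make_shapes([
        dict(theta_A=0.0, theta_J=170.0),   # folded |A-J| = 10 < 15: no
        dict(theta_A=0.0, theta_J=30.0),    # 30 >= 15: yes
        dict(C_A=0.7),                      # round
        dict(C_J=0.65),                     # elongated (<= 0.65)
        dict(theta_J=75.0),                 # >= 60 off stretch axis
    ])
    events = [event(i, 0.0) for i in range(5)]
    t = build_alignment_table(events, shapes)
    one_per = t[t.method == "junction"].set_index("cell_id")
    assert not one_per.loc[0, "flt_AJ15"]
    assert one_per.loc[1, "flt_AJ15"]
    assert one_per.loc[2, "flt_round_A"]
    assert one_per.loc[3, "flt_elong_J"]
    assert one_per.loc[4, "flt_J_off_stretch"]
    assert not one_per.loc[1, "flt_J_off_stretch"]


def test_alignment_all_aligned_and_exclusions():
    shapes = make_shapes([dict(theta_J=42.0) for _ in range(4)])
    events = [event(i, 42.0) for i in range(4)] + [event(99, 10.0)]
    t = build_alignment_table(events, shapes)
    assert np.allclose(t[t.method == "junction"]["diff"], 0.0)
    assert 99 not in set(t.cell_id)  # unmatched division excluded
    # degenerate reference axes are dropped
    shapes2 = make_shapes([dict(degenerate_J=True)])
    t2 = build_alignment_table([event(0, 0.0)], shapes2)
    assert "junction" not in set(t2.method)
    assert "area" in set(t2.method)


def test_alignment_hand_built_filter_counts():
    rng = np.random.default_rng(0)
    rows = []
    for k in range(20):
        rows.append(dict(theta_A=0.0, theta_J=float(k * 9 % 180),
                         C_A=0.5 + 0.03 * k, C_J=1.0 - 0.03 * k))
    shapes = make_shapes(rows)
    events = [event(i, float(rng.uniform(0, 180))) for i in range(20)]
    t = build_alignment_table(events, shapes)
    per = t[t.method == "junction"].set_index("cell_id")
    # enumerate expectations independently
    exp_aj = sum(fold_axial_difference(0.0, k * 9 % 180) >= 15 for k in range(20))
    exp_round = sum(0.5 + 0.03 * k > 0.65 for k in range(20))
    exp_elong = sum(1.0 - 0.03 * k <= 0.65 for k in range(20))
    assert per.flt_AJ15.sum() == exp_aj
    assert per.flt_round_A.sum() == exp_round
    assert per.flt_elong_J.sum() == exp_elong


# --------------------------------------------------------------- rank tests

def test_mannwhitney_perfect_alignment():
    res = mannwhitney_vs_uniform(np.zeros(50), seed=0)
    assert res.p_value < 1e-6


def test_mannwhitney_null_behaviour():
    rng = np.random.default_rng(1)
    ps = [mannwhitney_vs_uniform(rng.uniform(0, 90, 200), seed=k,
                                 n_reference=20000).p_value
          for k in range(200)]
    assert np.mean(ps) == pytest.approx(0.5, abs=0.06)


def test_mannwhitney_cdf_variant_agrees():
    rng = np.random.default_rng(2)
    d = rng.uniform(0, 30, 60)  # concentrated: both variants highly significant
    p_sample = mannwhitney_vs_uniform(d, seed=0).p_value
    p_cdf = mannwhitney_vs_uniform(d, reference="cdf").p_value
    assert p_sample < 1e-6 and p_cdf < 1e-6


def test_mannwhitney_input_validation():
    with pytest.raises(ValueError):
        mannwhitney_vs_uniform([1.0, 2.0])
    with pytest.raises(ValueError):
        mannwhitney_vs_uniform([10.0, 95.0, 20.0])


def test_ks_examples():
    # identical samples: D = 0, p = 1
    a = np.array([1.0, 5.0, 9.0, 13.0])
    res = ks_two_sample(a, a)
    assert res.statistic == 0.0 and res.p_value == 1.0
    # all-zero sample vs uniform: D -> 1
    res0 = ks_vs_uniform(np.zeros(40))
    assert res0.statistic > 0.97 and res0.p_value < 1e-10
    # evenly spaced grid: D = 1/(2n), comfortably non-significant
    n = 30
    grid = (np.arange(n) + 0.5) * 90.0 / n
    resg = ks_vs_uniform(grid)
    assert resg.statistic == pytest.approx(1.0 / (2 * n), abs=1e-12)
    assert resg.p_value > 0.99


def test_spearman_examples():
    x = np.arange(6, dtype=float)
    assert spearman_correlation(x, x**3).statistic == pytest.approx(1.0)
    assert spearman_correlation(x, -x).statistic == pytest.approx(-1.0)
    # hand-computed: ranks x = 1..6, y ranks of [3,1,2,6,4,5]
    y = np.array([30.0, 10.0, 20.0, 60.0, 40.0, 50.0])
    dsq = np.sum((np.arange(1, 7) - np.array([3, 1, 2, 6, 4, 5])) ** 2)
    rho_manual = 1 - 6 * dsq / (6 * (36 - 1))
    assert spearman_correlation(x, y).statistic == pytest.approx(rho_manual)
    with pytest.raises(ValueError):
        spearman_correlation(np.ones(6), x)


# ------------------------------------------------------------ division rates

def test_division_rate_arithmetic():
    rs = division_rate(n_divisions=6, n_cells=100, duration_hours=1.5,
                       unit="cell", seed=0)
    assert rs.rate == pytest.approx(4.0)
    assert rs.ci95[0] <= rs.rate <= rs.ci95[1]


def test_division_rate_zero_events():
    rs = division_rate(caps=[(100, 0), (80, 0)], duration_hours=2.0, seed=0)
    assert rs.rate == 0.0 and rs.ci95 == (0.0, 0.0)


def test_division_rate_bootstrap_calibration():
    """Per-cap bootstrap CIs cover the generating rate in >= 93% of runs
    (24 explants of 120 cells each, drawn at 6.47 %/h)."""
    true_rate, duration, n_caps, cells_per_cap = 6.47, 1.0, 24, 120
    rng = np.random.default_rng(3)
    p = true_rate / 100.0 * duration
    hits = 0
    reps = 500
    for r in range(reps):
        caps = [(cells_per_cap, int(rng.binomial(cells_per_cap, p)))
                for _ in range(n_caps)]
        rs = division_rate(caps=caps, duration_hours=duration, seed=r)
        if rs.ci95[0] <= true_rate <= rs.ci95[1]:
            hits += 1
    assert hits / reps >= 0.93


def test_division_rate_validation():
    with pytest.raises(ValueError):
        division_rate(n_divisions=1, n_cells=0, duration_hours=1.0, unit="cell")
    with pytest.raises(ValueError):
        division_rate(caps=[(10, 1)], duration_hours=0.0)


# ------------------------------------------------------- two-phase NEB fits

def test_phase_fit_exact_recovery():
    t = np.arange(0, 125, 5.0)
    y = np.where(t <= 50, 8.1 * t / 60.0, 8.1 * 50 / 60.0 + 4.35 * (t - 50) / 60.0)
    s1, s2, tb, rss = fit_neb_phases(t, y)
    assert s1 == pytest.approx(8.1, abs=1e-9)
    assert s2 == pytest.approx(4.35, abs=1e-9)
    assert tb == pytest.approx(50.0)
    assert rss < 1e-18


def test_phase_fit_single_slope():
    t = np.arange(0, 125, 5.0)
    y = 5.0 * t / 60.0
    s1, s2, _, _ = fit_neb_phases(t, y)
    assert s1 == pytest.approx(s2, abs=1e-9)
    assert s1 == pytest.approx(5.0, abs=1e-9)


def test_phase_fit_noisy_recovery():
    rng = np.random.default_rng(7)
    t = np.arange(0, 125, 2.5)
    clean = np.where(t <= 50, 8.1 * t / 60.0,
                     8.1 * 50 / 60.0 + 4.35 * (t - 50) / 60.0)
    y = np.maximum.accumulate(clean + rng.normal(0, 0.2, len(t)))
    s1, s2, _, _ = fit_neb_phases(t, y)
    assert s1 == pytest.approx(8.1, rel=0.10)
    assert s2 == pytest.approx(4.35, rel=0.10)


def test_phase_fit_validation():
    t = np.arange(0, 30, 5.0)
    with pytest.raises(ValueError):
        fit_neb_phases(t, np.sort(-t))  # decreasing
    with pytest.raises(ValueError):
        fit_neb_phases([0, 10, 20], [0, 1, 2])  # too few points
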