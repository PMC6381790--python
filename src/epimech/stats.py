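"""Division-orientation and proliferation statistics.

This is the quantification layer: per-division alignment tables with the
subpopulation filters used throughout the analysis (orientation
discrepancy >= 15 degrees, round cells C_A > 0.65, elongated cells
C_J <= 0.65, junction axis >= 60 degrees off the stretch axis), axial
rank statistics against a uniform reference, Kolmogorov-Smirnov and
Spearman tests, bootstrap division rates, and two-phase linear fits to
cumulative mitotic-entry curves.

All angle differences are axial, folded to [0, 90] degrees.  P-values
are reported raw (no multiple-testing correction), each alongside its n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .shape import DivisionEvent, fold_axial_difference

DEFAULT_FILTERS = {
    "axis_discrepancy_deg": 15.0,
    "round_ca": 0.65,
    "elongated_cj": 0.65,
    "off_stretch_deg": 60.0,
}


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    seed: int | None = None


@dataclass(frozen=True)
class RateSummary:
    """Division rate as percentage of cells entering mitosis per hour."""

    n_cells: int
    n_divisions: int
    duration: float  # hours
    rate: float      # % cells / hour
    ci95: tuple[float, float]


# ----------------------------------------------------------- alignment table

def build_alignment_table(divisions: list[DivisionEvent] | pd.DataFrame,
                          shapes: pd.DataFrame,
                          stresses: pd.DataFrame | None = None,
                          minc: pd.DataFrame | None = None,
                          filters: dict | None = None) -> pd.DataFrame:
    """One row per division and reference axis, with filter flags.

    ``shapes`` is the per-cell table from
    :func:`epimech.shape.characterize_tissue` (cell shape scored just
    before nuclear envelope breakdown); ``stresses``/``minc`` optionally
    add per-cell ``peff``/``xi`` and ``theta_minc`` columns.  Reference
    axes are theta_A / theta_P / theta_J (plus theta_Minc when supplied
    and the stretch axis at 0 degrees); ``diff`` is the axial difference
    |theta_D - theta_ref| in [0, 90].

    Filter flag columns (True = the division belongs to the
    subpopulation):

    - ``flt_AJ15``, ``flt_PJ15``, ``flt_MincJ15``: reference-axis
      discrepancy from theta_J of at least 15 degrees;
    - ``flt_round_A``: round cells, C_A > 0.65;
    - ``flt_elong_J``: elongated cells, C_J <= 0.65;
    - ``flt_J_off_stretch``: theta_J at least 60 degrees from the
      stretch axis.

    Divisions whose cell has no shape row, or whose reference axis is
    degenerate, are excluded (degenerate axes carry no orientation).
    """
    f = {**DEFAULT_FILTERS, **(filters or {})}
    if isinstance(divisions, pd.DataFrame):
        div_rows = [(int(r.cell_id), float(r.theta_d)) for r in divisions.itertuples()]
    else:
        div_rows = [(ev.cell_id, ev.theta_d) for ev in divisions]
    shapes = shapes.set_index("cell_id")
    if stresses is not None:
        stresses = stresses.set_index("cell_id")
    if minc is not None:
        minc = minc.set_index("cell_id")
    refs = [("area", "theta_A", "degenerate_A"),
            ("perimeter", "theta_P", "degenerate_P"),
            ("junction", "theta_J", "degenerate_J")]
    out = []
    for cell_id, theta_d in div_rows:
        if cell_id not in shapes.index:
            continue
        s = shapes.loc[cell_id]
        theta_minc, minc_degen = None, True
        if minc is not None and cell_id in minc.index:
            theta_minc = float(minc.loc[cell_id, "theta_minc"])
            minc_degen = bool(minc.loc[cell_id, "degenerate"])
        flags = {
            "flt_AJ15": (not s.degenerate_A and not s.degenerate_J
                         and fold_axial_difference(s.theta_A, s.theta_J)
                         >= f["axis_discrepancy_deg"]),
            "flt_PJ15": (not s.degenerate_P and not s.degenerate_J
                         and fold_axial_difference(s.theta_P, s.theta_J)
                         >= f["axis_discrepancy_deg"]),
            "flt_MincJ15": (theta_minc is not None and not minc_degen
                            and not s.degenerate_J
                            and fold_axial_difference(theta_minc, s.theta_J)
                            >= f["axis_discrepancy_deg"]),
            "flt_round_A": bool(s.C_A > f["round_ca"]),
            "flt_elong_J": bool(s.C_J <= f["elongated_cj"]),
            "flt_J_off_stretch": (not s.degenerate_J
                                  and fold_axial_difference(s.theta_J, 0.0)
                                  >= f["off_stretch_deg"]),
        }
        ref_axes = [(m, float(s[col]), bool(s[dcol])) for m, col, dcol in refs]
        if theta_minc is not None:
            ref_axes.append(("minc", theta_minc, minc_degen))
        ref_axes.append(("stretch", 0.0, False))
        for method, theta_ref, degen in ref_axes:
            if degen:
                continue
            row = {"cell_id": cell_id, "theta_d": theta_d, "method": method,
                   "theta_ref": theta_ref,
                   "diff": fold_axial_difference(theta_d, theta_ref),
                   "C_A": float(s.C_A), "C_P": float(s.C_P), "C_J": float(s.C_J)}
            if stresses is not None and cell_id in stresses.index:
                row["peff"] = float(stresses.loc[cell_id, "peff"])
                row["xi"] = float(stresses.loc[cell_id, "xi"])
            row.update(flags)
            out.append(row)
    return pd.DataFrame(out)


# ------------------------------------------------------------- rank statistics

def mannwhitney_vs_uniform(diffs, seed: int = 0, n_reference: int = 100000,
                           reference: str = "sample") -> TestResult:
    """One-sided Mann-Whitney U test: are axial differences closer to zero
    than a uniform [0, 90] distribution?

    ``reference="sample"`` compares against ``n_reference`` seeded uniform
    draws (ties by midranks); ``reference="cdf"`` uses the analytic
    uniform CDF via the one-sample Wilcoxon-like transform (each observed
    diff is ranked against the continuous uniform, equivalent to a
    one-sided test on the mean CDF value).  Small p-values mean the
    observed differences concentrate near zero.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 3:
        raise ValueError("need at least 3 differences")
    if np.any((diffs < 0) | (diffs > 90)):
        raise ValueError("axial differences must lie in [0, 90]")
    if reference == "sample":
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0.0, 90.0, size=n_reference)
        # asymptotic method: exact enumeration is intractable against the
        # large reference and the normal approximation is excellent there
        u, p = sps.mannwhitneyu(diffs, ref, alternative="less",
                                method="asymptotic")
        return TestResult("mannwhitney_vs_uniform", float(u), float(p),
                          len(diffs), seed)
    if reference == "cdf":
        # under H0 the CDF values U_i = diff_i/90 are iid uniform(0,1);
        # one-sided test of mean via the normal approximation
        u = diffs / 90.0
        z = (u.mean() - 0.5) / np.sqrt(1.0 / (12.0 * len(u)))
        p = float(sps.norm.cdf(z))
        return TestResult("mannwhitney_vs_uniform_cdf", float(z), p, len(diffs), None)
    raise ValueError(f"unknown reference {reference!r}")


def ks_vs_uniform(sample, domain: float = 90.0) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against uniform [0, domain]."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 3:
        raise ValueError("need at least 3 observations")
    res = sps.ks_1samp(sample, sps.uniform(loc=0.0, scale=domain).cdf)
    return TestResult("ks_vs_uniform", float(res.statistic), float(res.pvalue),
                      len(sample))


def ks_two_sample(sample_a, sample_b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (are two distributions different?)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")
    res = sps.ks_2samp(a, b)
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue),
                      len(a) + len(b))


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with midrank ties (e.g. C_J vs |theta_D - theta_J|)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), len(x))


# ------------------------------------------------------------ division rates

def division_rate(n_divisions: int | None = None, n_cells: int | None = None,
                  duration_hours: float = 1.0,
                  caps: list[tuple[int, int]] | None = None,
                  n_boot: int = 10000, seed: int = 0,
                  unit: str = "cap") -> RateSummary:
    """Division rate (% of cells entering mitosis per hour) with a
    percentile-bootstrap 95% CI.

    Provide either per-cap counts ``caps = [(n_cells, n_divisions), ...]``
    (the default resampling unit, one explant per point) or scalar totals
    with ``unit="cell"`` (cells resampled as Bernoulli indicators).
    """
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if caps is not None:
        caps = [(int(nc), int(nd)) for nc, nd in caps]
        n_cells = sum(nc for nc, _ in caps)
        n_divisions = sum(nd for _, nd in caps)
    if not n_cells:
        raise ValueError("need at least one cell")
    rate = 100.0 * n_divisions / (n_cells * duration_hours)
    if n_divisions == 0:
        return RateSummary(n_cells, 0, duration_hours, 0.0, (0.0, 0.0))
    if unit == "cap":
        if caps is None:
            raise ValueError('unit="cap" requires per-cap counts')
        arr = np.asarray(caps, dtype=float)
        idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
        tot = arr[idx].sum(axis=1)  # (n_boot, 2)
        rates = 100.0 * tot[:, 1] / (tot[:, 0] * duration_hours)
    elif unit == "cell":
        flags = np.zeros(n_cells)
        flags[:n_divisions] = 1.0
        idx = rng.integers(0, n_cells, size=(n_boot, n_cells))
        rates = 100.0 * flags[idx].mean(axis=1) / duration_hours
    else:
        raise ValueError(f"unknown resampling unit {unit!r}")
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return RateSummary(n_cells, n_divisions, duration_hours, float(rate),
                       (float(lo), float(hi)))


# ------------------------------------------------- two-phase cumulative fits

def fit_neb_phases(time_min, cumulative_pct,
                   breakpoint_window: tuple[float, float] = (40.0, 60.0)):
    """Two-phase linear fit to a cumulative mitotic-entry (%NEB) curve.

    Fits least-squares lines to the early ([0, t_break]) and late
    ([t_break, end]) segments, choosing t_break among the sample times
    inside ``breakpoint_window`` (minutes) to minimize the total residual
    sum of squares.  Returns ``(slope_early, slope_late, t_break, rss)``
    with slopes in % per hour.
    """
    t = np.asarray(time_min, float)
    y = np.asarray(cumulative_pct, float)
    if len(t) != len(y) or len(t) < 6:
        raise ValueError("need at least 6 samples")
    if np.any(np.diff(y) < -1e-9):
        raise ValueError("cumulative curve must be non-decreasing")
    lo, hi = breakpoint_window
    cands = np.unique(t[(t >= lo) & (t <= hi)])
    if len(cands) == 0:
        cands = np.array([0.5 * (lo + hi)])
    best = None
    for tb in cands:
        early = t <= tb
        late = t >= tb
        if early.sum() < 3 or late.sum() < 3:
            continue
        (s1, _), r1 = _lsq_line(t[early], y[early])
        (s2, _), r2 = _lsq_line(t[late], y[late])
        rss = r1 + r2
        if best is None or rss < best[0]:
            best = (rss, s1, s2, tb)
    if best is None:
        raise ValueError("no breakpoint leaves >=3 points per segment")
    rss, s1, s2, tb = best
    return 60.0 * s1, 60.0 * s2, float(tb), float(rss)


def _lsq_line(t, y):
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return (float(coef[0]), float(coef[1])), float(resid @ resid)
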