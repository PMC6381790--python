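"""Pipeline orchestration: geometry -> stress -> torque model -> statistics.

A :class:`PipelineConfig` (loadable from YAML) names the inputs, the
mechanical parameters (with ``a0="auto"`` triggering the preferred-area
calibration), the subpopulation filter thresholds, the statistical seeds
and the torque-model settings.  :func:`run_pipeline` executes the stages
in order, writes per-cell CSV tables and a machine-readable JSON summary,
and logs one structured line per stage (cell counts, exclusions,
degenerate flags).  The whole pipeline is a pure function of its inputs,
configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import minc as minc_mod
from .mesh import Tissue
from .shape import characterize_tissue
from .stats import (build_alignment_table, division_rate, ks_vs_uniform,
                    mannwhitney_vs_uniform, spearman_correlation)
from .stress import MechParams, cell_stress_tensor, classify_tension, fit_preferred_area
from .synth import divisions_from_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mesh: str = ""
    divisions: str | None = None
    out_dir: str = "epimech_out"
    lam: float = -0.259
    gamma: float = 0.172
    a0: float | str = "auto"
    filters: dict = field(default_factory=lambda: {
        "axis_discrepancy_deg": 15.0, "round_ca": 0.65,
        "elongated_cj": 0.65, "off_stretch_deg": 60.0})
    seed: int = 0
    n_reference: int = 100000
    bootstrap_reps: int = 10000
    minc_enabled: bool = True
    minc_betas: tuple = (3.0,)
    minc_rays: int = 180
    minc_grid: float = 1.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.pop(None, None)
        if "minc_betas" in d:
            d["minc_betas"] = tuple(d["minc_betas"])
        return cls(**d)


def stress_table(tissue: Tissue, params: MechParams) -> pd.DataFrame:
    """Per-cell stress table: peff, xi, principal axis, tension class."""
    deg = tissue.junction_degrees()
    boundary = tissue.boundary_cells()
    annotated = tissue.junction_degree is not None
    rows = []
    for i in range(tissue.n_cells):
        poly = tissue.cell_polygon(i)
        mask = (None if boundary[i] and not annotated
                else deg[tissue.cells[i]] >= 3)
        cs = cell_stress_tensor(poly, params, mask)
        rows.append({"cell_id": i, "peff": cs.peff, "xi": cs.xi,
                     "theta_sigma": cs.theta_sigma,
                     "tension_class": classify_tension(cs.peff),
                     "degenerate": cs.degenerate})
    return pd.DataFrame(rows)


def minc_table(tissue: Tissue, betas=(3.0,), n_rays: int = 180,
               grid: float = 1.0) -> pd.DataFrame:
    """Per-cell torque-model division-axis predictions, one row per cell
    per beta (force-length scaling exponent)."""
    rows = []
    for beta in betas:
        cfg = minc_mod.MincConfig(beta=beta, n_rays=n_rays, angle_grid=grid)
        for i in range(tissue.n_cells):
            pred = minc_mod.predict_division_axis(tissue.cell_polygon(i), cfg)
            rows.append({"cell_id": i, "beta": beta,
                         "theta_minc": pred.theta_minc,
                         "degenerate": pred.degenerate})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": dataclasses.asdict(config), "stages": {}}

    tissue = Tissue.from_json(config.mesh)
    tissue.validate()

    # ---- geometry
    shapes = characterize_tissue(tissue)
    shapes.to_csv(out / "shapes.csv", index=False)
    n_degen = int(shapes[["degenerate_A", "degenerate_P", "degenerate_J"]]
                  .any(axis=1).sum())
    logger.info("stage=geometry cells=%d degenerate=%d boundary=%d",
                len(shapes), n_degen, int(shapes.boundary.sum()))
    summary["stages"]["geometry"] = {"cells": len(shapes),
                                     "degenerate": n_degen}

    # ---- stress (with optional A0 calibration)
    if config.a0 == "auto":
        a0, resid = fit_preferred_area(tissue, config.lam, config.gamma)
        summary["stages"]["a0_fit"] = {"a0": a0, "p_tis_residual": resid}
        logger.info("stage=a0_fit a0=%.6g residual=%.3g", a0, resid)
    else:
        a0 = float(config.a0)
    params = MechParams(lam=config.lam, gamma=config.gamma, a0=a0)
    stresses = stress_table(tissue, params)
    stresses.to_csv(out / "stress.csv", index=False)
    counts = stresses.tension_class.value_counts().to_dict()
    logger.info("stage=stress cells=%d classes=%s", len(stresses), counts)
    summary["stages"]["stress"] = {"cells": len(stresses), "a0": a0,
                                   "tension_classes": counts}

    # ---- torque-model predictions
    minc_df = None
    if config.minc_enabled:
        minc_df = minc_table(tissue, config.minc_betas, config.minc_rays,
                             config.minc_grid)
        minc_df.to_csv(out / "minc.csv", index=False)
        logger.info("stage=minc cells=%d betas=%s degenerate=%d",
                    tissue.n_cells, list(config.minc_betas),
                    int(minc_df.degenerate.sum()))
        summary["stages"]["minc"] = {"rows": len(minc_df),
                                     "degenerate": int(minc_df.degenerate.sum())}

    # ---- alignment statistics
    if config.divisions:
        div_df = pd.read_csv(config.divisions)
        events = divisions_from_frame(div_df)
        minc_main = None
        if minc_df is not None and len(config.minc_betas):
            minc_main = minc_df[minc_df.beta == config.minc_betas[0]]
        table = build_alignment_table(events, shapes, stresses, minc_main,
                                      config.filters)
        table.to_csv(out / "alignment.csv", index=False)
        stats_out = _alignment_stats(table, config)
        summary["stages"]["alignment"] = stats_out
        logger.info("stage=alignment divisions=%d tests=%d", len(events),
                    len(stats_out.get("tests", [])))
    else:
        logger.info("stage=alignment skipped=no-divisions")
        summary["stages"]["alignment"] = {"skipped": "no division table supplied"}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _alignment_stats(table: pd.DataFrame, config: PipelineConfig) -> dict:
    tests = []
    if len(table) == 0:
        return {"tests": tests, "n_rows": 0}
    for method, sub in table.groupby("method"):
        d = sub["diff"].to_numpy()
        if len(d) >= 3:
            mw = mannwhitney_vs_uniform(d, seed=config.seed,
                                        n_reference=config.n_reference)
            ks = ks_vs_uniform(d)
            tests.append({"subset": f"all:{method}", "test": mw.test,
                          "statistic": mw.statistic, "p": mw.p_value,
                          "n": mw.n, "seed": config.seed})
            tests.append({"subset": f"all:{method}", "test": ks.test,
                          "statistic": ks.statistic, "p": ks.p_value, "n": ks.n})
    for flag in ("flt_AJ15", "flt_PJ15", "flt_MincJ15", "flt_round_A",
                 "flt_elong_J", "flt_J_off_stretch"):
        for method in ("area", "perimeter", "junction", "minc"):
            sub = table[(table[flag]) & (table.method == method)]
            if len(sub) >= 3:
                mw = mannwhitney_vs_uniform(sub["diff"].to_numpy(),
                                            seed=config.seed,
                                            n_reference=config.n_reference)
                tests.append({"subset": f"{flag}:{method}", "test": mw.test,
                              "statistic": mw.statistic, "p": mw.p_value,
                              "n": mw.n, "seed": config.seed})
    junc = table[table.method == "junction"]
    if len(junc) >= 4 and junc.C_J.nunique() > 1 and junc["diff"].nunique() > 1:
        sp = spearman_correlation(junc.C_J.to_numpy(), junc["diff"].to_numpy())
        tests.append({"subset": "junction", "test": sp.test,
                      "statistic": sp.statistic, "p": sp.p_value, "n": sp.n})
    return {"tests": tests, "n_rows": int(len(table))}


def rate_report(caps: list[tuple[int, int]], duration_hours: float,
                seed: int = 0, n_boot: int = 10000) -> dict:
    rs = division_rate(caps=caps, duration_hours=duration_hours,
                       n_boot=n_boot, seed=seed)
    return {"n_cells": rs.n_cells, "n_divisions": rs.n_divisions,
            "duration_h": rs.duration, "rate_pct_per_h": rs.rate,
            "ci95": list(rs.ci95), "seed": seed}


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
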