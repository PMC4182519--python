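"""End-to-end orchestration: simulate -> deprive -> aggregate -> decompose ->
robustness -> krige -> wealth, from a single configuration mapping, with a
machine-readable report.

The report deliberately contains no timestamps: a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .af_core import AFParams, aggregate, robustness_curve, subgroup_decomposition
from .deprivation import build_deprivation_matrix, serialize_specs
from .errors import ConfigError
from .geo import (
    aggregate_by_ea,
    empirical_variogram,
    fit_variogram,
    grid_to_geojson,
    krige,
    points_to_geojson,
)
from .synth import SimConfig, generate_survey
from .wealth import below_dollar_line, fit_wealth_model, quintile_flags, score_households

log = logging.getLogger("mdpoverty")

DEFAULT_CONFIG: dict = {
    "simulate": {},  # SimConfig overrides; omit and set "input" to use files
    "input": None,   # {"households": path, "eas": path}
    "af": {"k": "1/3", "inclusive": True},
    "k_grid": None,
    "groups": ["district", "stratum"],
    "variogram": {"family": "exponential", "n_bins": 12},
    "krige": {"nx": 100, "ny": 100, "per_district": True},
    "wealth": {"enabled": True, "n_quad": 21, "max_iter": 500},
    "confidence": 0.95,
    "seed": 0,
    "out_dir": None,
}

#: minimal schema for report.json: required key -> expected type
REPORT_SCHEMA: dict = {
    "package_version": str,
    "seed": int,
    "config": dict,
    "versions": dict,
    "overall": dict,
    "groups": dict,
    "robustness": list,
    "ea_estimates": list,
    "kriging": dict,
    "wealth": dict,
}


def validate_report(report: dict) -> None:
    """Raise if the report is missing required keys or has wrong types."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ConfigError(f"report is missing required key '{key}'")
        if not isinstance(report[key], typ):
            raise ConfigError(
                f"report key '{key}' has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )


def load_config(source) -> dict:
    """Merge a YAML path / mapping over the defaults."""
    if source is None:
        user = {}
    elif isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        user = source
    else:
        raise ConfigError("config must be a path or a mapping")
    cfg = {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if k not in cfg:
            raise ConfigError(f"unknown configuration key '{k}'")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _af_params(cfg: dict) -> AFParams:
    k = cfg["af"].get("k", "1/3")
    return AFParams(k=Fraction(str(k)), inclusive=bool(cfg["af"].get("inclusive", True)))


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config=None, out_dir=None) -> dict:
    """Run all stages; write artifacts when an output directory is set.

    Returns the report mapping.  Any stage failure propagates with the
    stage named in the log.
    """
    cfg = load_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    seed = int(cfg["seed"])
    conf = float(cfg["confidence"])
    out = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage: data ---
    log.info("stage=data")
    if cfg["input"]:
        households = pd.read_csv(cfg["input"]["households"])
        eas = pd.read_csv(cfg["input"]["eas"])
        sim_cfg = None
    else:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        if "target_marginals" in sim_kwargs:
            sim_kwargs["target_marginals"] = tuple(sim_kwargs["target_marginals"])
        sim_cfg = SimConfig(**sim_kwargs)
        tables = generate_survey(sim_cfg)
        households, eas = tables.households, tables.eas
        if out is not None:
            tables.write(out)

    # fail fast: grouping columns must exist
    for g in cfg["groups"]:
        if g not in households.columns:
            raise ConfigError(f"grouping column '{g}' not found in household table")

    # --- stage: deprivation matrix ---
    log.info("stage=deprivation")
    m = build_deprivation_matrix(households)
    if out is not None:
        m.to_frame().to_csv(out / "g0.csv", index=False)
        (out / "indicator_specs.json").write_text(
            json.dumps(serialize_specs(), indent=2)
        )

    # --- stage: AF aggregation and decomposition ---
    log.info("stage=aggregate")
    params = _af_params(cfg)
    overall = aggregate(m, params, conf)
    groups_block: dict = {}
    for g in cfg["groups"]:
        dec = subgroup_decomposition(m, households[g].to_numpy(), params, conf)
        groups_block[g] = {
            str(name): {"share": blk["share"], **blk["result"].as_dict()}
            for name, blk in dec.items()
        }

    # --- stage: robustness curve ---
    log.info("stage=robustness")
    k_grid = cfg["k_grid"]
    if k_grid is not None:
        k_grid = [Fraction(str(k)) for k in k_grid]
    curve = robustness_curve(m, k_grid, inclusive=params.inclusive, confidence=conf)
    if out is not None:
        curve.to_csv(out / "robustness.csv", index=False)

    # --- stage: spatial surfaces ---
    log.info("stage=krige")
    ea_est = aggregate_by_ea(m, params, ea_table=eas)
    emp = empirical_variogram(
        ea_est[["x", "y"]].to_numpy(),
        ea_est["m0"].to_numpy(),
        n_bins=int(cfg["variogram"].get("n_bins", 12)),
    )
    model = fit_variogram(emp, cfg["variogram"].get("family", "exponential"))
    kcfg = cfg["krige"]
    nx, ny = int(kcfg.get("nx", 100)), int(kcfg.get("ny", 100))
    surfaces = []
    if kcfg.get("per_district", True) and "district" in ea_est.columns:
        for dname, sub in ea_est.groupby("district", sort=True):
            if len(sub) < 2:
                log.warning("district %s has < 2 EAs; skipping kriging", dname)
                continue
            surf = krige(sub, model, (nx, ny))
            surf.grid["district"] = dname
            surfaces.append(surf)
    else:
        surfaces.append(krige(ea_est, model, (nx, ny)))
    surface_grid = pd.concat([s.grid for s in surfaces], ignore_index=True)
    max_weight_dev = max(s.max_weight_dev for s in surfaces)
    if out is not None:
        cols = ["ea_id", "m0", "n_households"] + (
            ["district"] if "district" in ea_est.columns else []
        )
        (out / "ea_m0.geojson").write_text(
            json.dumps(points_to_geojson(ea_est, props=cols))
        )
        surface_grid.to_csv(out / "surface.csv", index=False)
        (out / "surface.geojson").write_text(
            json.dumps(
                points_to_geojson(
                    surface_grid,
                    props=["m0_pred", "m0_pred_clamped", "ok_variance"]
                    + (["district"] if "district" in surface_grid.columns else []),
                )
            )
        )

    # --- stage: wealth index ---
    log.info("stage=wealth")
    wealth_block: dict = {"enabled": bool(cfg["wealth"].get("enabled", True))}
    if wealth_block["enabled"]:
        item_cols = [c for c in households.columns if c.startswith("asset_")]
        items = households[item_cols].to_numpy()
        wm = fit_wealth_model(
            items,
            max_iter=int(cfg["wealth"].get("max_iter", 500)),
            n_quad=int(cfg["wealth"].get("n_quad", 21)),
        )
        scores = score_households(items, wm)
        s = 1.0 / households["sampling_probability"].to_numpy(float)
        lowest = quintile_flags(scores, s)
        below = below_dollar_line(
            households["monthly_income_mzn"].to_numpy(float),
            households["household_size"].to_numpy(float),
        )
        poor_mask = None
        wealth_df = pd.DataFrame(
            {
                "household_id": households["household_id"],
                "wealth_score": scores,
                "lowest_quintile": lowest,
                "below_125_line": below,
            }
        )
        if out is not None:
            wealth_df.to_csv(out / "wealth.csv", index=False)
        wealth_block.update(
            {
                "converged": bool(wm.converged),
                "n_iter": int(wm.n_iter),
                "n_items_used": int(len(wm.kept_items)),
                "pct_below_125_line": float(np.average(below, weights=s)) * 100,
                "pct_zero_income": float(
                    np.average(
                        households["monthly_income_mzn"].to_numpy(float) == 0, weights=s
                    )
                )
                * 100,
                "pct_lowest_quintile": float(np.average(lowest, weights=s)) * 100,
            }
        )

    report = {
        "package_version": __version__,
        "seed": seed,
        "config": _round_floats(
            json.loads(
                json.dumps({k: v for k, v in cfg.items() if k != "out_dir"}, default=str)
            )
        ),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "overall": _round_floats(overall.as_dict()),
        "groups": _round_floats(groups_block),
        "robustness": _round_floats(curve.to_dict(orient="records")),
        "ea_estimates": _round_floats(
            ea_est[["ea_id", "m0", "n_households"]].to_dict(orient="records")
        ),
        "kriging": _round_floats(
            {
                "family": model.model,
                "nugget": model.nugget,
                "partial_sill": model.partial_sill,
                "range": model.range_param,
                "max_weight_dev": max_weight_dev,
                "n_grid_nodes": int(len(surface_grid)),
            }
        ),
        "wealth": _round_floats(wealth_block),
    }
    validate_report(report)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def summarize(report: dict) -> str:
    """Human-readable markdown summary of headline poverty measures."""
    validate_report(report)

    def fmt(block: dict) -> str:
        ci = block.get("ci_H") or (float("nan"), float("nan"))
        return (
            f"{block['H']:.3f} ({ci[0]:.3f}, {ci[1]:.3f}) | "
            f"{block['A']:.3f} | {block['M0']:.3f}"
        )

    lines = [
        "| group | H (95% CI) | A | M0 |",
        "|---|---|---|---|",
        f"| overall | {fmt(report['overall'])} |",
    ]
    for gvar, groups in report["groups"].items():
        for name, blk in sorted(groups.items()):
            lines.append(f"| {gvar}={name} | {fmt(blk)} |")
    dims = report["overall"].get("dimension_contributions")
    if dims:
        order = sorted(dims.items(), key=lambda kv: -kv[1])
        lines.append("")
        lines.append(
            "Dimension contributions to M0: "
            + ", ".join(f"{k} {v * 100:.1f}%" for k, v in order)
        )
    w = report.get("wealth", {})
    if w.get("enabled"):
        lines.append(
            f"Households below $1.25/day: {w['pct_below_125_line']:.1f}%; "
            f"zero income: {w['pct_zero_income']:.1f}%."
        )
    return "\n".join(lines)
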