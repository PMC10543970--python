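"""End-to-end campaign driver: simulate → reconcile → derive → train →
select → evaluate → sensitivity → baseline → report.

The driver generates a labelled synthetic campaign, reconciles the raw
channels, derives off-gas rates and the windowed growth-rate signal,
assembles per-task feature tables, sweeps the engine × hidden-node grid,
selects the minimum-RMSE model, evaluates it on the held-out run against
the simulator truth and the offline samples, runs the connection-weight
sensitivity analysis, and fits the multiple-linear-regression baseline for
comparison.  Every number in the report is recomputable from the stored
seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann as ann_mod
from .ann import (
    BATCH_BIOMASS_FEATURES,
    FEDBATCH_BIOMASS_FEATURES,
    GROWTH_RATE_FEATURES,
    AnnSpec,
    FitGrid,
    evaluate,
    grid_search,
    predict_growth_rate_chain,
    select_best,
)
from .kinetics import compute_cer, compute_our, compute_rq, estimate_growth_rate
from .mlr import fit_mlr, predict_mlr
from .reconcile import FilterSpec, filter_signal, fit_tcd_calibration, reconcile
from .sensitivity import mean_effects
from .simulate import CampaignConfig, CampaignRun, generate_campaign
from .training import train_ann

__all__ = ["PipelineConfig", "build_feature_table", "run_campaign", "load_config"]

RAW_CHANNELS = ["do_pct", "tcd_au", "o2_out_pct", "co2_out_pct"]


@dataclass
class PipelineConfig:
    """Everything the campaign driver needs; YAML-serializable."""

    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    engines: tuple = ann_mod.ENGINES
    nodes: tuple = tuple(range(1, 16))
    restarts: int = 5
    goal: float = 1e-3
    max_epochs: int | None = None
    sensitivity_retrainings: int = 3
    mlr_alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["campaign"]["params"]["gas"] = dataclasses.asdict(self.campaign.params.gas)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    from .kinetics import GasConditions
    from .simulate import SimulatorParams

    camp_kw = dict(raw.get("campaign", {}))
    params_kw = dict(camp_kw.pop("params", {}))
    gas_kw = dict(params_kw.pop("gas", {}))
    if gas_kw:
        params_kw["gas"] = GasConditions(**gas_kw)
    if params_kw:
        camp_kw["params"] = SimulatorParams(**params_kw)
    filt_kw = dict(raw.get("filter", {}))
    top = {
        k: raw[k]
        for k in (
            "engines",
            "nodes",
            "restarts",
            "goal",
            "max_epochs",
            "sensitivity_retrainings",
            "mlr_alpha",
        )
        if k in raw
    }
    for k in ("engines", "nodes"):
        if k in top:
            top[k] = tuple(top[k])
    return PipelineConfig(
        campaign=CampaignConfig(**camp_kw),
        filter=FilterSpec(**filt_kw) if filt_kw else FilterSpec(),
        **top,
    )


def build_feature_table(run: CampaignRun, spec: FilterSpec | None = None) -> pd.DataFrame:
    """Reconciled feature table for one run.

    Raw channels are filtered first; OUR/CER/RQ and the windowed growth
    rate are derived from the reconciled channels and then filtered again
    with the same window.  Media descriptors are constant columns.
    Undefined RQ samples (vanishing OUR) are filled from the nearest
    defined sample.
    """
    spec = spec or FilterSpec()
    gas = run.params.gas
    rec = reconcile(run.series, RAW_CHANNELS, spec)
    f = rec.frame
    our = filter_signal(compute_our(rec, gas), spec)
    cer = filter_signal(compute_cer(rec, gas), spec)
    rq = compute_rq(our, cer, gas)
    rq = pd.Series(rq).ffill().bfill().to_numpy()
    rq = filter_signal(rq, spec) if np.isfinite(rq).all() else rq
    media = run.media
    table = pd.DataFrame(
        {
            "run_id": run.run_id,
            "time_h": f["time_h"],
            "lactose": media.lactose,
            "total_carbon_solids": media.total_carbon_solids,
            "total_solids": media.total_solids,
            "inoculum_size": media.inoculum_size,
            "do_pct": f["do_pct"],
            "base_cum_ml": f["base_cum_ml"],
            "tcd_au": f["tcd_au"],
            "our": our,
            "cer": cer,
            "rq": rq,
            "volume_l": f["volume_l"],
            "biomass_gl": f["biomass_gl"],
            "mu_h": f["mu_true"],
        }
    )
    return table.dropna().reset_index(drop=True)


def _pool(runs, mode, role, spec):
    picked = [r for r in runs if r.mode == mode and r.role == role]
    if not picked:
        return None
    return pd.concat(
        [build_feature_table(r, spec) for r in picked], ignore_index=True
    )


def _usable_features(table: pd.DataFrame, names) -> tuple[list, list]:
    """Split requested features into usable and (constant → dropped)."""
    usable, dropped = [], []
    for n in names:
        if np.ptp(table[n].to_numpy()) < 1e-12:
            dropped.append(n)
        else:
            usable.append(n)
    return usable, dropped


def _tcd_biomass_estimate(run: CampaignRun, spec: FilterSpec) -> np.ndarray:
    """Classical estimator: per-run calibrated, reconciled TCD biomass."""
    rec = reconcile(run.series, ["tcd_au"], spec)
    t = rec.frame["time_h"].to_numpy()
    au = rec.frame["tcd_au"].to_numpy()
    off = run.offline.frame
    au_at = np.interp(off["time_h"], t, au)
    cal = fit_tcd_calibration(au_at, off["cdw_gl"], media_label=str(run.run_id))
    return np.maximum(cal.gain * au + cal.offset, 0.0)


def _train_task(
    task_name,
    feature_spec,
    train_table,
    holdout_run,
    holdout_table,
    config: PipelineConfig,
    seed: int,
    upstream_model=None,
):
    """Grid-search one task and evaluate on the held-out run."""
    names, dropped = _usable_features(train_table, feature_spec.inputs)
    x = train_table.loc[:, names].to_numpy(dtype=float)
    y = train_table[feature_spec.output].to_numpy(dtype=float)
    grid = grid_search(
        x,
        y,
        engines=config.engines,
        nodes=config.nodes,
        seed=seed,
        restarts=config.restarts,
        goal=config.goal,
        max_epochs=config.max_epochs,
    )
    sel = select_best(grid)
    model = grid.model(sel.engine, sel.n_hidden)
    model.feature_names = tuple(names)
    model.output_name = feature_spec.output

    result = {
        "task": task_name,
        "features": names,
        "dropped_constant_features": dropped,
        "selected": sel._asdict(),
        "split_metrics": model.metrics,
        "grid": grid.frame.to_dict("records"),
    }

    if holdout_run is not None:
        yh = holdout_table[feature_spec.output].to_numpy(dtype=float)
        pred = model.forward(holdout_table.loc[:, names].to_numpy(dtype=float))
        rmse_t, r2_t = evaluate(yh, pred)
        off = holdout_run.offline.frame
        pred_at = np.interp(off["time_h"], holdout_table["time_h"], pred)
        if feature_spec.output == "biomass_gl":
            rmse_o, r2_o = evaluate(off["cdw_gl"], pred_at)
            result["holdout_vs_offline"] = {"rmse": rmse_o, "r2": r2_o}
        result["holdout_vs_truth"] = {"rmse": rmse_t, "r2": r2_t}

        # MLR baseline on the identical training rows and features
        mlr = fit_mlr(train_table.loc[:, names], y, alpha=config.mlr_alpha)
        mlr_pred = predict_mlr(mlr, holdout_table.loc[:, names])
        m_rmse, m_r2 = evaluate(yh, mlr_pred)
        result["mlr"] = {
            "intercept": mlr.intercept,
            "coefficients": mlr.coefficients,
            "dropped_terms": mlr.dropped,
            "overall_p": mlr.overall_p,
            "train_rmse": mlr.rmse,
            "holdout_vs_truth": {"rmse": m_rmse, "r2": m_r2},
        }

    sens_spec = AnnSpec(
        n_inputs=len(names),
        n_hidden=sel.n_hidden,
        engine=sel.engine,
        goal=config.goal,
        max_epochs=config.max_epochs,
        restarts=max(1, config.restarts // 2),
        seed=seed + 17,
    )
    try:
        sens = mean_effects(
            sens_spec, x, y, n=config.sensitivity_retrainings,
            feature_names=names,
        )
        result["sensitivity"] = {
            "inputs": list(sens.inputs),
            "effects": sens.effects.tolist(),
            "se": sens.se.tolist(),
            "n_retrainings": sens.n_retrainings,
        }
    except Exception as exc:  # sensitivity failure is not fatal to the task
        result["sensitivity"] = {"error": str(exc)}
    return result, model, grid


def run_campaign(
    config: PipelineConfig | None = None, seed: int = 0, outdir=None
) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    config = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    manifest = {"seed": int(seed), "config_hash": config.config_hash(), "stages": []}

    def _stage(name):
        manifest["stages"].append({"stage": name, "status": "ok"})

    def _fail(name, exc):
        manifest["stages"].append({"stage": name, "status": f"failed: {exc}"})
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True)
            )

    report = {
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "tasks": {},
        "runs": [],
    }
    try:
        runs = generate_campaign(config.campaign, seed)
        _stage("simulate")
    except Exception as exc:
        _fail("simulate", exc)
        raise
    for r in runs:
        report["runs"].append(
            {
                "run_id": r.run_id,
                "mode": r.mode,
                "role": r.role,
                "seed": r.seed,
                "mu_set": r.mu_set,
                "overflow": bool(r.series.meta.get("overflow", False)),
            }
        )
    if out is not None:
        rundir = out / "runs"
        rundir.mkdir(parents=True, exist_ok=True)
        for r in runs:
            r.series.to_csv(rundir / f"run_{r.run_id:02d}.csv")
            r.offline.to_csv(rundir / f"run_{r.run_id:02d}_offline.csv")

    models, grids = {}, {}
    tasks = []
    if sum(1 for r in runs if r.mode == "batch") >= 2:
        tasks.append(("batch_biomass", BATCH_BIOMASS_FEATURES, "batch"))
    if sum(1 for r in runs if r.mode == "fedbatch") >= 2:
        tasks.append(("fedbatch_biomass", FEDBATCH_BIOMASS_FEATURES, "fedbatch"))
        tasks.append(("growth_rate", GROWTH_RATE_FEATURES, "fedbatch"))

    for task_name, feature_spec, mode in tasks:
        try:
            train_table = _pool(runs, mode, "train", config.filter)
            holdout_run = next(
                (r for r in runs if r.mode == mode and r.role == "test"), None
            )
            holdout_table = (
                build_feature_table(holdout_run, config.filter)
                if holdout_run is not None
                else None
            )
            if task_name == "growth_rate":
                fed_model = models.get("fedbatch_biomass")
                if fed_model is None:
                    raise RuntimeError(
                        "growth-rate task needs the fed-batch biomass model"
                    )
                for tbl in (train_table, holdout_table):
                    if tbl is not None:
                        tbl["ann_predicted_biomass"] = fed_model.forward(
                            tbl.loc[:, list(fed_model.feature_names)].to_numpy(float)
                        )
            result, model, grid = _train_task(
                task_name,
                feature_spec,
                train_table,
                holdout_run,
                holdout_table,
                config,
                seed + {"batch_biomass": 0, "fedbatch_biomass": 100,
                        "growth_rate": 200}[task_name],
            )
            # classical TCD estimator on the held-out run for comparison
            if holdout_run is not None and feature_spec.output == "biomass_gl":
                tcd_est = _tcd_biomass_estimate(holdout_run, config.filter)
                truth = holdout_run.series.frame["biomass_gl"].to_numpy()
                rm, r2 = evaluate(truth, tcd_est)
                result["tcd_probe_vs_truth"] = {"rmse": rm, "r2": r2}
            report["tasks"][task_name] = result
            models[task_name] = model
            grids[task_name] = grid
            _stage(f"train:{task_name}")
        except Exception as exc:
            _fail(f"train:{task_name}", exc)
            raise

    if "growth_rate" in models and "fedbatch_biomass" in models:
        try:
            holdout_run = next(
                (r for r in runs if r.mode == "fedbatch" and r.role == "test"), None
            )
            if holdout_run is not None:
                tbl = build_feature_table(holdout_run, config.filter)
                mu_pred = predict_growth_rate_chain(
                    models["fedbatch_biomass"], models["growth_rate"], tbl
                )
                rm, r2 = evaluate(tbl["mu_h"], mu_pred)
                report["tasks"]["growth_rate"]["chained_holdout_vs_truth"] = {
                    "rmse": rm,
                    "r2": r2,
                }
            _stage("chain")
        except Exception as exc:
            _fail("chain", exc)
            raise

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for name, model in models.items():
            model.to_json(out / f"model_{name}.json")
        for name, grid in grids.items():
            grid.to_csv(out / f"grid_{name}.csv")
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True)
        )
        manifest["stages"].append({"stage": "report", "status": "ok"})
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
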