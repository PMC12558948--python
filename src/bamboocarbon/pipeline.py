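"""End-to-end pipeline: simulate -> sample -> interpolate -> validate ->
select -> fit -> map -> report.

Configuration is a nested dictionary (typically loaded from YAML) validated
against a fixed key set before any stage runs. Every artifact embeds the
configuration hash and the seed, so a rerun with the same configuration
reproduces every CSV byte-for-byte. Stages always run in order up to the
requested stage; since everything is deterministic, rerunning earlier
stages is cheap and keeps the driver idempotent.
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

from . import geostatistics, io, mapping, modeling, sampling, scene, tps, validation
from .grids import read_asc

log = logging.getLogger(__name__)

STAGES = ("simulate", "sample", "interp-tps", "interp-ck", "validate",
          "select", "fit", "map", "report")

_ALLOWED_KEYS = {
    "scene": None,  # validated by SceneConfig itself
    "sampling": {"interval", "offset", "rules"},
    "spline": {"orders", "variables"},
    "kriging": {"n_lags", "neighborhood", "variables"},
    "validate": {"variables"},
    "model": {"families", "n_folds", "seed", "importance_seed", "one_se"},
    "mapping": {"clip_negative"},
    "out_dir": None,
    "seed": None,
    "log_level": None,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; see ``from_dict`` for the schema."""

    scene: scene.SceneConfig
    out_dir: Path
    sampling: dict = field(default_factory=dict)
    spline: dict = field(default_factory=dict)
    kriging: dict = field(default_factory=dict)
    validate: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_ALLOWED_KEYS)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        for section, allowed in _ALLOWED_KEYS.items():
            if allowed and section in raw:
                extra = set(raw[section]) - allowed
                if extra:
                    raise ValueError(
                        f"unknown key(s) in {section!r}: {sorted(extra)}")
        seed = int(raw.get("seed", 0))
        scene_kw = dict(raw.get("scene", {}))
        scene_kw.setdefault("seed", seed)
        if "extent" in scene_kw:
            scene_kw["extent"] = tuple(scene_kw["extent"])
        if "dbh_lognormal" in scene_kw:
            scene_kw["dbh_lognormal"] = tuple(scene_kw["dbh_lognormal"])
        if "parameters" in scene_kw:
            scene_kw["parameters"] = {
                name: (spec if isinstance(spec, scene.ParameterFieldSpec)
                       else scene.ParameterFieldSpec(**spec)
                       if isinstance(spec, dict)
                       else scene.ParameterFieldSpec(*spec))
                for name, spec in scene_kw["parameters"].items()}
        cfg = cls(
            scene=scene.SceneConfig(**scene_kw),
            out_dir=Path(raw.get("out_dir", "bamboocarbon_run")),
            sampling=dict(raw.get("sampling", {})),
            spline=dict(raw.get("spline", {})),
            kriging=dict(raw.get("kriging", {})),
            validate=dict(raw.get("validate", {})),
            model=dict(raw.get("model", {})),
            mapping=dict(raw.get("mapping", {})),
            seed=seed,
            log_level=raw.get("log_level", "INFO"),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def metadata(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["out_dir"] = str(self.out_dir)
        return {"config_hash": io.config_hash(raw), "seed": self.seed}


def run_pipeline(config: PipelineConfig, upto: str = "report") -> dict:
    """Execute the pipeline through stage ``upto``; returns artifact paths.

    Any stage failure aborts with the stage name; artifacts written before
    the failure are preserved on disk.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()
    artifacts: dict[str, Path] = {}
    ctx: dict = {}
    last = STAGES.index(upto)
    for stage in STAGES[:last + 1]:
        log.info("pipeline stage: %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out, meta, ctx, artifacts)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _spline_variables(config: PipelineConfig) -> list[str]:
    return list(config.spline.get("variables")
                or config.scene.parameters.keys())


def _stage_simulate(config, out, meta, ctx, artifacts):
    truth, footprints, plots = scene.generate_scene(config.scene)
    ctx["truth"], ctx["footprints"], ctx["plots"] = truth, footprints, plots
    truth.dem.write_asc(out / "dem.asc", meta)
    artifacts["dem"] = out / "dem.asc"
    for name, grid in truth.parameter_fields.items():
        grid.write_asc(out / f"truth_{name}.asc", meta)
    truth.agc_field.write_asc(out / "truth_agc.asc", meta)
    io.write_footprint_csv(footprints, out / "footprints.csv", meta)
    io.write_plot_csv(plots, out / "plots.csv", meta)
    artifacts["footprints"] = out / "footprints.csv"
    artifacts["plots"] = out / "plots.csv"


def _stage_sample(config, out, meta, ctx, artifacts):
    table = ctx["footprints"]
    rules = {k: tuple(v) for k, v in config.sampling.get("rules", {}).items()}
    table = sampling.quality_filter(table, rules)
    table = sampling.systematic_sample(table,
                                       config.sampling.get("interval", 1),
                                       config.sampling.get("offset"))
    ctx["sampled"] = table
    io.write_footprint_csv(table, out / "footprints_sampled.csv", meta)
    artifacts["footprints_sampled"] = out / "footprints_sampled.csv"


def _stage_interp_tps(config, out, meta, ctx, artifacts):
    table = ctx["sampled"]
    dem = ctx["truth"].dem
    orders = tuple(config.spline.get("orders", (2, 3, 4)))
    pts = table[["x", "y"]].to_numpy()
    elev = table["elevation"].to_numpy()
    rows = []
    surfaces = {}
    for name in _spline_variables(config):
        fits = {}
        cands = []
        for m in orders:
            fit = tps.fit_partial_spline(pts, table[name].to_numpy(), elev,
                                         order_m=m, smoothing="gcv")
            diag = tps.diagnostics(fit)
            fits[m] = fit
            cands.append((m, diag))
            rows.append({"variable": name, "order": m, "signal": diag.signal,
                         "error": diag.error_df, "snr": diag.snr,
                         "gcv": diag.gcv, "msr": diag.msr, "var": diag.var,
                         "rtgcv": diag.rtgcv, "rtmsr": diag.rtmsr,
                         "rtvar": diag.rtvar, "star": diag.star_flag})
        best = tps.select_spline_order(cands, n_obs=len(table))
        grid = tps.rasterize(fits[best], dem)
        surfaces[name] = grid
        grid.write_asc(out / f"tps_{name}.asc", {**meta, "order": best})
        rows.append({"variable": name, "order": best, "signal": np.nan,
                     "error": np.nan, "snr": np.nan, "gcv": np.nan,
                     "msr": np.nan, "var": np.nan, "rtgcv": np.nan,
                     "rtmsr": np.nan, "rtvar": np.nan, "star": "selected"})
    ctx["tps_surfaces"] = surfaces
    io._write_csv(pd.DataFrame(rows), out / "tps_diagnostics.csv", meta)
    artifacts["tps_diagnostics"] = out / "tps_diagnostics.csv"


def _stage_interp_ck(config, out, meta, ctx, artifacts):
    table = ctx["sampled"]
    dem = ctx["truth"].dem
    pts = table[["x", "y"]].to_numpy()
    elev = table["elevation"].to_numpy()
    gx, gy = dem.cell_centres()
    mask = dem.mask()
    targets = np.column_stack([gx[mask], gy[mask]])
    variables = list(config.kriging.get("variables")
                     or _spline_variables(config))
    nb = config.kriging.get("neighborhood", 16)
    rows = []
    surfaces = {}
    for name in variables:
        z = table[name].to_numpy()
        g11, g22, g12 = geostatistics.fit_cokriging_models(
            pts, z, elev, n_lags=config.kriging.get("n_lags", 12))
        for label, model in (("primary", g11), ("secondary", g22),
                             ("cross", g12)):
            rows.append({"variable": name, "role": label,
                         "model": model.model_type, "C0": model.nugget,
                         "sill": model.sill,
                         "ratio_pct": (100 * model.nugget / model.sill
                                       if model.sill else np.nan),
                         "range_m": model.range_m, "RSS": model.rss,
                         "R2": model.r2})
        pred, se = geostatistics.cokrige(pts, z, elev, (g11, g22), g12,
                                         targets, neighborhood=nb)
        grid_v = np.full(dem.values.shape, dem.nodata)
        grid_v[mask] = pred
        grid = dem.copy_with(grid_v)
        surfaces[name] = grid
        grid.write_asc(out / f"ck_{name}.asc", meta)
        se_v = np.full(dem.values.shape, dem.nodata)
        se_v[mask] = se
        dem.copy_with(se_v).write_asc(out / f"ck_{name}_se.asc", meta)
    ctx["ck_surfaces"] = surfaces
    io._write_csv(pd.DataFrame(rows), out / "variograms.csv", meta)
    artifacts["variograms"] = out / "variograms.csv"


def _stage_validate(config, out, meta, ctx, artifacts):
    table = ctx["sampled"]
    pts = table[["x", "y"]].to_numpy()
    elev = table["elevation"].to_numpy()
    variables = list(config.validate.get("variables")
                     or _spline_variables(config))
    reports = {}
    for name in variables:
        z = table[name].to_numpy()
        reports[name] = {
            "tps": validation.loo_crossvalidate("tps", pts, z, elev),
            "ck": validation.loo_crossvalidate("ck", pts, z, elev,
                                               config.kriging),
        }
    comparison = validation.compare_methods(reports)
    ctx["cv_comparison"] = comparison
    io._write_csv(comparison, out / "interp_cv.csv",
                  {**meta, "overall_winner":
                   comparison.attrs.get("overall_winner", "n/a")})
    artifacts["interp_cv"] = out / "interp_cv.csv"


def _stage_select(config, out, meta, ctx, artifacts):
    features = modeling.extract_features(ctx["tps_surfaces"], ctx["plots"])
    ctx["features"] = features
    predictors = features.drop(columns=["plot_id", "agc_mg_ha"])
    ranking = modeling.oob_permutation_importance(
        predictors, features["agc_mg_ha"],
        seed=config.model.get("importance_seed", config.seed))
    n_folds = min(config.model.get("n_folds", 10), len(features))
    selected, curve = modeling.progressive_selection(
        ranking, predictors, features["agc_mg_ha"],
        modeling.ModelSpec("rfr", seed=config.seed),
        {"n_folds": n_folds, "seed": config.seed,
         "one_se": config.model.get("one_se", False)})
    ctx["selected"] = selected
    io._write_csv(ranking, out / "importance.csv", meta)
    (out / "selection.json").write_text(json.dumps(
        {"selected": selected, "rmse_curve": curve, **meta}, indent=1))
    artifacts["importance"] = out / "importance.csv"
    artifacts["selection"] = out / "selection.json"


def _stage_fit(config, out, meta, ctx, artifacts):
    features = ctx["features"]
    selected = ctx["selected"]
    y = features["agc_mg_ha"]
    n_folds = min(config.model.get("n_folds", 10), len(features))
    rows = []
    metrics = {}
    for family in config.model.get("families",
                                   ("lightgbm", "rfr", "xgboost")):
        spec = modeling.ModelSpec(family, seed=config.seed)
        m = modeling.crossval_metrics(features[selected], y, spec,
                                      n_folds=n_folds, seed=config.seed)
        metrics[family] = m
        rows.append({"model": family, "R2": m.r2, "RMSE": m.rmse,
                     "P": m.p_pct, "rRMSE": m.rrmse_pct})
    best = max(metrics, key=lambda f: metrics[f].r2)
    for family, m in metrics.items():
        if family != best:
            rows.append({
                "model": f"{best} vs {family}",
                "R2": modeling.relative_improvement(metrics[best].r2, m.r2),
                "RMSE": modeling.relative_improvement(
                    metrics[best].rmse, m.rmse, "lower_better"),
                "P": modeling.relative_improvement(metrics[best].p_pct,
                                                   m.p_pct),
                "rRMSE": modeling.relative_improvement(
                    metrics[best].rrmse_pct, m.rrmse_pct, "lower_better")})
    ctx["best_family"] = best
    ctx["model_metrics"] = metrics
    io._write_csv(pd.DataFrame(rows), out / "model_metrics.csv", meta)
    artifacts["model_metrics"] = out / "model_metrics.csv"


def _stage_map(config, out, meta, ctx, artifacts):
    features = ctx["features"]
    selected = ctx["selected"]
    spec = modeling.ModelSpec(ctx["best_family"], seed=config.seed)
    model = modeling.fit_regressor(features[selected], features["agc_mg_ha"],
                                   spec)
    agc = mapping.predict_raster(
        model, ctx["tps_surfaces"], feature_names=selected,
        clip_negative=config.mapping.get("clip_negative", True))
    agc.write_asc(out / "agc_map.asc", meta)
    summary = mapping.zonal_summary(agc)
    (out / "agc_summary.json").write_text(json.dumps(
        {**dataclasses.asdict(summary), **meta}, indent=1))
    ctx["agc_map"] = agc
    ctx["agc_summary"] = summary
    artifacts["agc_map"] = out / "agc_map.asc"
    artifacts["agc_summary"] = out / "agc_summary.json"


def _stage_report(config, out, meta, ctx, artifacts):
    summary = ctx["agc_summary"]
    report = {
        "n_footprints": int(len(ctx["sampled"])),
        "n_plots": int(len(ctx["plots"])),
        "selected_variables": ctx["selected"],
        "best_model": ctx["best_family"],
        "model_metrics": {f: dataclasses.asdict(m)
                          for f, m in ctx["model_metrics"].items()},
        "interp_overall_winner":
            ctx["cv_comparison"].attrs.get("overall_winner", "n/a"),
        "agc_mean_mg_ha": summary.mean,
        "agc_total_mg": summary.total_stock,
        **meta,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    artifacts["report"] = out / "report.json"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sample": _stage_sample,
    "interp-tps": _stage_interp_tps,
    "interp-ck": _stage_interp_ck,
    "validate": _stage_validate,
    "select": _stage_select,
    "fit": _stage_fit,
    "map": _stage_map,
    "report": _stage_report,
}
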