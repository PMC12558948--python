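"""Leave-one-out cross-validation of the two interpolators.

Each interpolation method (partial thin-plate spline, ordinary co-kriging)
is scored by refitting without each point in turn and predicting it, then
summarising with four metrics:

* ME        mean error, mean(pred - obs)
* RMSE      root mean squared error
* MSE       mean *standardized* error, mean((pred - obs) / se) — the
            cross-validation vocabulary of GIS packages, which is why
            published tables show negative values
* ASE       average standard error, mean(se)

A good interpolator has ME and MSE near 0, small RMSE, and ASE close to
RMSE (the error model is neither over- nor under-confident).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geostatistics, tps

log = logging.getLogger(__name__)


@dataclass
class CVReport:
    """Per-point LOO results and the four summary metrics for one method."""

    method: str
    observed: np.ndarray
    predicted: np.ndarray
    prediction_se: np.ndarray
    failed: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.failed is None:
            self.failed = np.zeros(len(self.observed), dtype=bool)
        if not (len(self.observed) == len(self.predicted)
                == len(self.prediction_se) == len(self.failed)):
            raise ValueError("per-point arrays must have equal length")

    @property
    def metrics(self) -> tuple[float, float, float, float]:
        ok = ~self.failed
        return cv_metrics(self.observed[ok], self.predicted[ok],
                          self.prediction_se[ok])


def cv_metrics(observed, predicted, se) -> tuple[float, float, float, float]:
    """(ME, RMSE, MSE_std, ASE) for pooled cross-validation results."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    se = np.asarray(se, dtype=float)
    if obs.size == 0:
        raise ValueError("empty cross-validation result")
    err = pred - obs
    me = float(err.mean())
    rmse = float(np.sqrt(np.mean(err ** 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        std_err = np.where(se > 0, err / se, 0.0)
    return me, rmse, float(std_err.mean()), float(se.mean())


def loo_crossvalidate(method: str, points, values, covariates=None,
                      config: dict | None = None) -> CVReport:
    """Leave-one-out cross-validation for ``method`` in {"tps", "ck"}.

    TPS: the smoothing parameter is selected once by GCV on the full data
    and held fixed across folds; prediction standard errors come from the
    full fit as sqrt(VAR * A_ii). CK: variogram models are fitted once on
    the full data; each fold solves the co-kriging system without point i,
    returning the kriging standard error. Failed folds are flagged and
    excluded from the metrics.
    """
    config = dict(config or {})
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 points for LOO cross-validation")
    cov = None if covariates is None else np.asarray(covariates, dtype=float)

    pred = np.full(n, np.nan)
    se = np.full(n, np.nan)
    failed = np.zeros(n, dtype=bool)

    if method == "tps":
        order_m = config.get("order_m", 2)
        full = tps.fit_partial_spline(pts, z, cov, order_m=order_m,
                                      smoothing=config.get("smoothing", "gcv"))
        diag = tps.diagnostics(full)
        a_diag = full.design.influence_diag(full.p_smooth)
        se[:] = np.sqrt(np.clip(diag.var * a_diag, 0.0, None))
        keep_mask = np.ones(n, dtype=bool)
        for i in range(n):
            keep_mask[i] = False
            try:
                fold = tps.fit_partial_spline(
                    pts[keep_mask], z[keep_mask],
                    None if cov is None else cov[keep_mask],
                    order_m=order_m, smoothing=full.p_smooth)
                pred[i] = tps.predict(
                    fold, pts[i:i + 1],
                    None if cov is None else cov[i:i + 1])[0]
            except tps.SplineFitError as exc:
                failed[i] = True
                log.warning("TPS LOO fold %d failed: %s", i, exc)
            keep_mask[i] = True
    elif method == "ck":
        if cov is None:
            raise ValueError("co-kriging needs the secondary variable")
        sec = cov.ravel()
        g11, g22, g12 = geostatistics.fit_cokriging_models(
            pts, z, sec, n_lags=config.get("n_lags", 12),
            max_dist=config.get("max_dist"))
        nb = config.get("neighborhood", 16)
        keep_mask = np.ones(n, dtype=bool)
        for i in range(n):
            keep_mask[i] = False
            try:
                p, s = geostatistics.cokrige(
                    pts[keep_mask], z[keep_mask], sec[keep_mask],
                    (g11, g22), g12, pts[i:i + 1], neighborhood=nb)
                pred[i], se[i] = p[0], s[0]
            except np.linalg.LinAlgError as exc:
                failed[i] = True
                log.warning("CK LOO fold %d failed: %s", i, exc)
            keep_mask[i] = True
    else:
        raise ValueError(f"unknown interpolation method {method!r}")

    return CVReport(method=method, observed=z, predicted=pred,
                    prediction_se=se, failed=failed)


def compare_methods(reports: dict) -> pd.DataFrame:
    """Side-by-side metric table for two methods across variables.

    ``reports`` maps variable name -> {method -> CVReport}. Per variable the
    method with smaller |ME|, smaller RMSE and smaller |ASE - RMSE| is
    flagged; the overall winner takes the majority of flags. Variables
    missing a method are excluded with a warning.
    """
    rows = []
    for variable, by_method in reports.items():
        if len(by_method) < 2:
            log.warning("compare_methods: %s present for one method only; "
                        "excluded", variable)
            continue
        metrics = {m: rep.metrics for m, rep in by_method.items()}
        methods = list(metrics)
        me = {m: abs(v[0]) for m, v in metrics.items()}
        rmse = {m: v[1] for m, v in metrics.items()}
        ase_gap = {m: abs(v[3] - v[1]) for m, v in metrics.items()}

        def _winner(score):
            vals = [score[m] for m in methods]
            if len(set(vals)) == 1:
                return "tie"
            return min(methods, key=lambda m: score[m])

        for m in methods:
            me_, rmse_, mse_, ase_ = metrics[m]
            rows.append({"variable": variable, "method": m, "ME": me_,
                         "RMSE": rmse_, "MSE": mse_, "ASE": ase_,
                         "wins_me": _winner(me) == m,
                         "wins_rmse": _winner(rmse) == m,
                         "wins_ase_gap": _winner(ase_gap) == m})
    table = pd.DataFrame(rows)
    if len(table):
        wins = table.groupby("method")[
            ["wins_me", "wins_rmse", "wins_ase_gap"]].sum().sum(axis=1)
        best = wins.idxmax()
        table.attrs["overall_winner"] = (
            "tie" if (wins == wins.max()).sum() > 1 else best)
    return table
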