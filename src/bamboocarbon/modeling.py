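"""Plot-level AGC regression: features, importance ranking, model scoring.

The regression stage links the interpolated parameter surfaces to the plot
inventory: predictor values are sampled at plot centres, variables are
ranked by out-of-bag (OOB) permutation importance from a random forest
(%IncMSE), a prefix of the ranking is chosen by progressive addition
against cross-validated RMSE, and three gradient/bagging families
(LightGBM, random forest, XGBoost) are compared by ten-fold
cross-validation with

    R^2 = 1 - SSE/SST,  RMSE = sqrt(SSE/n),
    rRMSE = 100 * RMSE / mean(obs),  P = 100 - rRMSE.

Shipped hyperparameter defaults are the grid-search optima of the study
design: LightGBM num_leaves 20 / max_depth 5 / learning_rate 0.1, random
forest mtry 9 / ntree 200, XGBoost nrounds 45 / max_depth 3 / eta 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

log = logging.getLogger(__name__)

DEFAULT_HYPERPARAMETERS = {
    "lightgbm": {"num_leaves": 20, "max_depth": 5, "learning_rate": 0.1,
                 "n_estimators": 100},
    "rfr": {"mtry": 9, "ntree": 200},
    "xgboost": {"nrounds": 45, "max_depth": 3, "eta": 0.1},
}


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus hyperparameters; unspecified ones take the
    shipped defaults for that family."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def resolved(self) -> dict:
        if self.family not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown model family {self.family!r}")
        hp = dict(DEFAULT_HYPERPARAMETERS[self.family])
        hp.update(self.hyperparameters)
        return hp


@dataclass(frozen=True)
class ModelMetrics:
    """Pooled cross-validation scores; P and rRMSE are complementary."""

    r2: float
    rmse: float
    p_pct: float
    rrmse_pct: float


def extract_features(surfaces: dict, plots: pd.DataFrame,
                     response: str = "agc_mg_ha") -> pd.DataFrame:
    """Sample every surface at the plot centres (bilinear) and join the
    response; plots over nodata or outside the extent are dropped with a
    warning."""
    georefs = list(surfaces.values())
    for g in georefs[1:]:
        if not g.same_georef(georefs[0]):
            raise ValueError("predictor surfaces must share georeferencing")
    out = pd.DataFrame({"plot_id": plots["plot_id"].to_numpy()})
    xs, ys = plots["x"].to_numpy(float), plots["y"].to_numpy(float)
    for name, grid in surfaces.items():
        out[name] = grid.sample_bilinear(xs, ys)
    out[response] = plots[response].to_numpy(float)
    bad = out.drop(columns=["plot_id"]).isna().any(axis=1)
    if bad.any():
        log.warning("extract_features: dropped %d plots over nodata or "
                    "outside the extent", int(bad.sum()))
    return out[~bad].reset_index(drop=True)


# ----------------------------------------------------------------------
# random-forest OOB permutation importance
# ----------------------------------------------------------------------

def oob_permutation_importance(features: pd.DataFrame, response,
                               rfr_spec: ModelSpec | None = None,
                               n_repeats: int = 1,
                               seed: int = 0) -> pd.DataFrame:
    """Rank predictors by %IncMSE from a bagged regression forest.

    Each tree is grown on a bootstrap sample; for every predictor the
    increase in OOB MSE after permuting that column is recorded per tree.
    %IncMSE is the mean increase divided by its standard error across trees,
    times 100 (0 when the increase never varies). IncNodePurity sums the
    weighted impurity decrease credited to each predictor over all trees.
    Returns a frame sorted descending by pct_inc_mse.
    """
    spec = rfr_spec or ModelSpec("rfr")
    hp = spec.resolved()
    X = features.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if p < 2 or n < 10:
        raise ValueError("need >= 2 predictors and >= 10 rows")
    ntree = hp["ntree"]
    mtry = min(hp["mtry"], p)
    rng = np.random.default_rng([seed, spec.seed])

    deltas = np.full((ntree, p), np.nan)
    purity = np.zeros(p)
    for t in range(ntree):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            random_state=int(rng.integers(0, 2 ** 31 - 1)))
        tree.fit(X[boot], y[boot])
        purity += _node_purity(tree, p)
        if oob.size == 0:
            continue
        base = np.mean((tree.predict(X[oob]) - y[oob]) ** 2)
        for j in range(p):
            inc = 0.0
            for _ in range(n_repeats):
                Xp = X[oob].copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                inc += np.mean((tree.predict(Xp) - y[oob]) ** 2) - base
            deltas[t, j] = inc / n_repeats

    rows = []
    for j, name in enumerate(features.columns):
        dj = deltas[:, j]
        dj = dj[~np.isnan(dj)]
        if dj.size == 0:
            log.warning("variable %s never OOB-evaluable; importance 0", name)
            pct = 0.0
        else:
            sd = dj.std(ddof=1) if dj.size > 1 else 0.0
            se = sd / np.sqrt(dj.size)
            pct = 100.0 * dj.mean() / se if se > 0 else 0.0
        rows.append({"variable": name, "pct_inc_mse": pct,
                     "inc_node_purity": purity[j]})
    return (pd.DataFrame(rows)
            .sort_values("pct_inc_mse", ascending=False, kind="stable")
            .reset_index(drop=True))


def _node_purity(tree: DecisionTreeRegressor, p: int) -> np.ndarray:
    """Summed weighted impurity decrease per feature for one fitted tree."""
    t = tree.tree_
    out = np.zeros(p)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        dec = (t.weighted_n_node_samples[node] * t.impurity[node]
               - t.weighted_n_node_samples[left] * t.impurity[left]
               - t.weighted_n_node_samples[right] * t.impurity[right])
        out[t.feature[node]] += dec
    return out


# ----------------------------------------------------------------------
# model fitting and scoring
# ----------------------------------------------------------------------

def fit_regressor(features, response, spec: ModelSpec):
    """Fit one regression model; returns an object exposing ``predict``."""
    hp = spec.resolved()
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    if spec.family == "lightgbm":
        import lightgbm
        model = lightgbm.LGBMRegressor(
            num_leaves=hp["num_leaves"], max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            n_estimators=hp["n_estimators"],
            random_state=spec.seed, n_jobs=1, verbose=-1,
            deterministic=True, force_col_wise=True)
    elif spec.family == "rfr":
        from sklearn.ensemble import RandomForestRegressor
        model = RandomForestRegressor(
            n_estimators=hp["ntree"],
            max_features=min(hp["mtry"], X.shape[1]),
            random_state=spec.seed, n_jobs=1)
    elif spec.family == "xgboost":
        import xgboost
        model = xgboost.XGBRegressor(
            n_estimators=hp["nrounds"], max_depth=hp["max_depth"],
            learning_rate=hp["eta"], random_state=spec.seed, n_jobs=1)
    else:
        raise ValueError(f"unknown model family {spec.family!r}")
    model.fit(X, y)
    return model


def pooled_metrics(observed, predicted) -> ModelMetrics:
    """R^2 / RMSE / P / rRMSE of pooled predictions against observations."""
    y = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    sse = float(np.sum((pred - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / len(y)))
    if y.mean() == 0:
        raise ZeroDivisionError("mean response is zero: rRMSE undefined")
    rrmse = 100.0 * rmse / float(y.mean())
    return ModelMetrics(r2=1.0 - sse / sst, rmse=rmse,
                        p_pct=100.0 - rrmse, rrmse_pct=rrmse)


def crossval_metrics(features, response, spec: ModelSpec,
                     n_folds: int = 10, seed: int = 0) -> ModelMetrics:
    """Ten-fold (by default) cross-validation with pooled out-of-fold
    predictions; fold assignment is a seeded random permutation."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    if n_folds < 2 or len(y) < n_folds:
        raise ValueError("need n_folds >= 2 and at least n_folds rows")
    oof = np.full(len(y), np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        model = fit_regressor(X[train], y[train], spec)
        oof[test] = model.predict(X[test])
    return pooled_metrics(y, oof)


def progressive_selection(ranking: pd.DataFrame, features: pd.DataFrame,
                          response, model_spec: ModelSpec,
                          cv_config: dict | None = None):
    """Add variables in ranking order and track cross-validated RMSE.

    Returns (selected_variables, rmse_curve) where the curve is a list of
    (k, rmse). The argmin-k prefix wins, ties to the smaller k; with
    ``one_se: True`` in cv_config the smallest k within one standard error
    of the minimum is chosen instead (off by default).
    """
    cv = dict(cv_config or {})
    n_folds = cv.get("n_folds", 10)
    seed = cv.get("seed", 0)
    order = list(ranking["variable"])
    missing = set(features.columns) - set(order)
    if missing:
        raise ValueError(f"ranking does not cover columns {sorted(missing)}")
    y = np.asarray(response, dtype=float)

    curve = []
    for k in range(1, len(order) + 1):
        try:
            m = crossval_metrics(features[order[:k]], y, model_spec,
                                 n_folds=n_folds, seed=seed)
            curve.append((k, m.rmse))
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("progressive_selection: k=%d skipped (%s)", k, exc)
    if not curve:
        raise RuntimeError("every prefix size failed")
    ks = np.array([c[0] for c in curve])
    rmses = np.array([c[1] for c in curve])
    best = int(np.argmin(rmses))
    if cv.get("one_se", False):
        se = rmses.std(ddof=1) / np.sqrt(len(rmses)) if len(rmses) > 1 else 0.0
        ok = rmses <= rmses[best] + se
        best = int(np.argmax(ok))  # first (smallest k) within one SE
    return order[:int(ks[best])], curve


def relative_improvement(new_value: float, base_value: float,
                         orientation: str = "higher_better") -> float:
    """Percent improvement of ``new_value`` over ``base_value``."""
    if base_value == 0:
        raise ZeroDivisionError("zero baseline: relative improvement undefined")
    if orientation == "higher_better":
        return 100.0 * (new_value - base_value) / base_value
    if orientation == "lower_better":
        return 100.0 * (base_value - new_value) / base_value
    raise ValueError(f"unknown orientation {orientation!r}")
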