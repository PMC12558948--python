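"""Semivariograms, variogram-model fitting and ordinary co-kriging.

Co-kriging (CK) is the geostatistical counterpart of the spline surface
fitting in :mod:`bamboocarbon.tps`: the LiDAR parameter is the primary
variable and elevation the cross-correlated secondary. The empirical
semivariogram gamma(h) = (1/2N(h)) sum (a_i - a_j)(b_i - b_j) is estimated in
distance bins, a nugget/sill/range model is fitted by pair-count-weighted
least squares, and the ordinary co-kriging system is solved per target with
the usual unbiasedness constraints (primary weights sum to 1, secondary to 0).

Model forms (h >= 0, nugget C0, partial sill C, range a):

* Spherical:    C0 + C * (1.5 h/a - 0.5 (h/a)^3) for h <= a, C0 + C beyond
* Exponential:  C0 + C * (1 - exp(-h/a))
* Gaussian:     C0 + C * (1 - exp(-h^2/a^2))   (practical range sqrt(3) a)

The nugget ratio 100 * C0/(C0+C) classifies spatial autocorrelation:
< 25 % strong, 25-75 % moderate, > 75 % weak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)


class VariogramFitError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# model forms
# ----------------------------------------------------------------------

def _model_gamma(model_type: str, h, c0, c, a):
    h = np.asarray(h, dtype=float)
    if model_type == "Spherical":
        hh = np.minimum(h / a, 1.0)
        g = c0 + c * (1.5 * hh - 0.5 * hh ** 3)
    elif model_type == "Exponential":
        g = c0 + c * (1.0 - np.exp(-h / a))
    elif model_type == "Gaussian":
        g = c0 + c * (1.0 - np.exp(-(h / a) ** 2))
    else:
        raise ValueError(f"unknown variogram model {model_type!r}")
    # gamma(0) = 0 by definition; the nugget is the limit from the right
    return np.where(h > 0, g, 0.0)


@dataclass
class EmpiricalVariogram:
    """Binned semivariance estimates with pair counts."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    kind: str = "direct"

    def nonempty(self) -> "EmpiricalVariogram":
        sel = self.counts > 0
        return EmpiricalVariogram(self.lags[sel], self.gamma[sel],
                                  self.counts[sel], self.kind)


@dataclass
class VariogramModel:
    """Fitted nugget/sill/range triple with fit quality."""

    model_type: str
    nugget: float           # C0
    partial_sill: float     # C
    range_m: float          # a
    rss: float = float("nan")
    r2: float = float("nan")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        return _model_gamma(self.model_type, h, self.nugget,
                            self.partial_sill, self.range_m)


def empirical_semivariogram(points, values_a, values_b=None,
                            lag_width: float | None = None,
                            max_dist: float | None = None,
                            n_lags: int = 12) -> EmpiricalVariogram:
    """Binned (cross-)semivariogram estimator.

    With ``values_b`` given the cross form (1/2N(h)) sum (da * db) is used;
    otherwise the direct form with da = db. Defaults: ``max_dist`` is half
    the maximum pairwise distance, split into ``n_lags`` equal bins.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    a = np.asarray(values_a, dtype=float)
    b = a if values_b is None else np.asarray(values_b, dtype=float)
    kind = "direct" if values_b is None else "cross"

    d = pdist(pts)
    if max_dist is None:
        max_dist = float(d.max()) / 2.0
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if lag_width is None:
        lag_width = max_dist / n_lags
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")
    n_bins = max(int(np.ceil(max_dist / lag_width - 1e-9)), 1)
    edges = lag_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], max_dist)

    iu, ju = np.triu_indices(len(pts), k=1)
    prod = 0.5 * (a[iu] - a[ju]) * (b[iu] - b[ju])
    which = np.digitize(d, edges) - 1
    valid = (d > 0) & (which >= 0) & (which < len(edges) - 1)

    n_bins = len(edges) - 1
    counts = np.bincount(which[valid], minlength=n_bins)
    sums = np.bincount(which[valid], weights=prod[valid], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if np.any(counts == 0):
        log.info("empirical_semivariogram: %d empty bins flagged",
                 int((counts == 0).sum()))
    return EmpiricalVariogram(centres, gamma, counts, kind)


def fit_variogram(emp: EmpiricalVariogram, model_type: str) -> VariogramModel:
    """Fit (C0, C, a) by pair-count-weighted least squares.

    RSS is the N(h)-weighted squared-residual sum; R^2 is computed on the
    same weighting against the weighted mean. C0 and C are constrained
    non-negative, so degenerate negative-sill candidates surface as fit
    failures rather than invalid models.
    """
    ne = emp.nonempty()
    if len(ne.lags) < 3:
        raise VariogramFitError("need at least three non-empty lag bins")
    h, g, n = ne.lags, ne.gamma, ne.counts.astype(float)
    sw = np.sqrt(n)

    def residuals(theta):
        c0, c, a = theta
        return sw * (_model_gamma(model_type, h, c0, c, a) - g)

    g_rng = max(g.max() - g.min(), 1e-12)
    x0 = np.array([max(g.min(), 1e-12 * g_rng), max(g.max() - g.min(), 1e-12),
                   h[len(h) // 2]])
    sol = least_squares(residuals, x0,
                        bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]))
    if not sol.success:
        raise VariogramFitError(f"{model_type} fit failed: {sol.message}")
    c0, c, a = sol.x
    res = residuals(sol.x)
    rss = float(np.sum(res ** 2))
    gbar = np.sum(n * g) / np.sum(n)
    ss_tot = float(np.sum(n * (g - gbar) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    return VariogramModel(model_type, float(c0), float(c), float(a), rss, r2)


def nugget_ratio(model: VariogramModel) -> float:
    """Nugget ratio 100 * C0 / (C0 + C) in percent."""
    if model.sill == 0:
        raise ZeroDivisionError("zero sill: nugget ratio undefined")
    return 100.0 * model.nugget / model.sill


def classify_autocorrelation(ratio_pct: float) -> str:
    """Spatial-autocorrelation class from the nugget ratio (percent)."""
    if not 0 <= ratio_pct <= 100:
        raise ValueError("nugget ratio must lie in [0, 100]")
    if ratio_pct < 25:
        return "strong"
    if ratio_pct <= 75:
        return "moderate"
    return "weak"


def best_variogram(emp: EmpiricalVariogram,
                   candidates=("Gaussian", "Spherical", "Exponential")
                   ) -> VariogramModel:
    """Fit every candidate model and return the one with maximal R^2
    (ties broken by minimal RSS); failed fits are skipped."""
    fits = []
    for model_type in candidates:
        try:
            fits.append(fit_variogram(emp, model_type))
        except VariogramFitError as exc:
            log.warning("best_variogram: %s", exc)
    if not fits:
        raise VariogramFitError("every candidate model failed to fit")
    return max(fits, key=lambda m: (m.r2, -m.rss))


# ----------------------------------------------------------------------
# co-kriging
# ----------------------------------------------------------------------

def _check_coregionalisation(direct_primary: VariogramModel,
                             direct_secondary: VariogramModel,
                             cross: VariogramModel) -> VariogramModel:
    """Clip the cross-structure so the linear model of coregionalisation is
    positive semi-definite (|b12| <= sqrt(b11 b22) per structure)."""
    c0_max = np.sqrt(direct_primary.nugget * direct_secondary.nugget)
    c_max = np.sqrt(direct_primary.partial_sill * direct_secondary.partial_sill)
    c0, c = cross.nugget, cross.partial_sill
    clipped = False
    if abs(c0) > c0_max:
        c0 = np.sign(c0) * c0_max
        clipped = True
    if abs(c) > c_max:
        c = np.sign(c) * c_max
        clipped = True
    if clipped:
        warnings.warn("cross-variogram violates positive semi-definiteness; "
                      "sills projected onto the admissible bound",
                      stacklevel=3)
        return VariogramModel(cross.model_type, c0, c, cross.range_m,
                              cross.rss, cross.r2)
    return cross


def cokrige(points, primary_values, secondary_values,
            direct_models: tuple[VariogramModel, VariogramModel],
            cross_model: VariogramModel, targets,
            neighborhood: int = 16):
    """Ordinary co-kriging with one co-located secondary variable.

    Solves, per target, the semivariogram form of the ordinary CK system on
    the ``neighborhood`` nearest data points: primary weights sum to 1,
    secondary weights sum to 0. Returns (predictions, standard_errors).
    A singular neighbourhood system is retried once with a doubled
    neighbourhood before raising.
    """
    pts = np.asarray(points, dtype=float)
    z1 = np.asarray(primary_values, dtype=float)
    z2 = np.asarray(secondary_values, dtype=float)
    tg = np.atleast_2d(np.asarray(targets, dtype=float))
    g11, g22 = direct_models
    g12 = _check_coregionalisation(g11, g22, cross_model)

    n = len(pts)
    k = min(neighborhood, n)
    tree = cKDTree(pts)
    preds = np.empty(len(tg))
    ses = np.empty(len(tg))
    dmat = squareform(pdist(pts))

    for t, x0 in enumerate(tg):
        for attempt, kk in enumerate((k, min(2 * k, n))):
            idx = tree.query(x0, k=kk)[1]
            idx = np.atleast_1d(idx)
            m = len(idx)
            h = dmat[np.ix_(idx, idx)]
            h0 = np.linalg.norm(pts[idx] - x0, axis=1)
            A = np.zeros((2 * m + 2, 2 * m + 2))
            A[:m, :m] = g11.gamma(h)
            A[:m, m:2 * m] = g12.gamma(h)
            A[m:2 * m, :m] = g12.gamma(h)
            A[m:2 * m, m:2 * m] = g22.gamma(h)
            A[:m, 2 * m] = 1.0
            A[m:2 * m, 2 * m + 1] = 1.0
            A[2 * m, :m] = 1.0
            A[2 * m + 1, m:2 * m] = 1.0
            b = np.concatenate([g11.gamma(h0), g12.gamma(h0), [1.0, 0.0]])
            try:
                sol = np.linalg.solve(A, b)
                break
            except np.linalg.LinAlgError:
                if attempt == 1:
                    raise
        lam, mu = sol[:m], sol[m:2 * m]
        preds[t] = lam @ z1[idx] + mu @ z2[idx]
        var = float(lam @ g11.gamma(h0) + mu @ g12.gamma(h0) + sol[2 * m])
        ses[t] = np.sqrt(max(var, 0.0))
    return preds, ses


def fit_cokriging_models(points, primary_values, secondary_values,
                         n_lags: int = 12, max_dist: float | None = None,
                         candidates=("Gaussian", "Spherical", "Exponential")):
    """Convenience: fit direct models for both variables plus the cross model.

    The primary's best direct model is selected by R^2; the secondary direct
    and the cross model are then fitted under the same structure type and
    range (minimal linear model of coregionalisation), leaving only their
    nugget and partial sill free.
    """
    emp1 = empirical_semivariogram(points, primary_values, max_dist=max_dist,
                                   n_lags=n_lags)
    best1 = best_variogram(emp1, candidates)

    def _fit_fixed_range(emp):
        ne = emp.nonempty()
        h, g, nc = ne.lags, ne.gamma, ne.counts.astype(float)
        sw = np.sqrt(nc)
        base = _model_gamma(best1.model_type, h, 0.0, 1.0, best1.range_m)
        X = np.column_stack([sw * np.ones_like(h), sw * base])
        coef, *_ = np.linalg.lstsq(X, sw * g, rcond=None)
        c0, c = coef
        if emp.kind == "direct":  # direct structures must be non-negative
            c0, c = max(c0, 0.0), max(c, 0.0)
        return VariogramModel(best1.model_type, float(c0), float(c),
                              best1.range_m)

    emp2 = empirical_semivariogram(points, secondary_values,
                                   max_dist=max_dist, n_lags=n_lags)
    emp12 = empirical_semivariogram(points, primary_values, secondary_values,
                                    max_dist=max_dist, n_lags=n_lags)
    direct2 = _fit_fixed_range(emp2)
    cross = _check_coregionalisation(best1, direct2, _fit_fixed_range(emp12))
    return best1, direct2, cross
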