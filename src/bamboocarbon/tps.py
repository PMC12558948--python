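"""Partial thin-plate smoothing splines with a linear covariate.

The interpolation model for a LiDAR parameter z observed at footprint i is

    z_i = f(x_i) + b^T y_i + e_i

with f a smooth bivariate function of the projected coordinates, y_i a linear
covariate vector (here elevation) and e_i noise. f and b minimise the
penalised weighted least squares criterion

    sum_i [(z_i - f(x_i) - b^T y_i) / w_i]^2 + p * J_m(f)

where J_m is the order-m thin-plate roughness penalty and p the smoothing
parameter. For d = 2 the minimiser is a radial-basis expansion in the kernel
r^(2m-2) log r plus a polynomial null space of total degree <= m-1
(dimension 3/6/10 for m = 2/3/4) and the covariate column. The smoothing
parameter is chosen by generalized cross-validation (GCV):

    GCV(p) = (||W^-1 (I - A) z||^2 / N) / (tr(I - A) / N)^2

with A the influence matrix (z_hat = A z). Fit diagnostics mirror the
ANUSPLIN log vocabulary: Signal = tr(A) (surface degrees of freedom),
Error = N - tr(A), SNR = Signal/Error, MSR, VAR and their square roots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

log = logging.getLogger(__name__)

NULL_SPACE_DIM = {2: 3, 3: 6, 4: 10}


class SplineFitError(RuntimeError):
    """Raised when the spline system is singular or under-determined."""


class OrderSelectionError(RuntimeError):
    """Raised when every candidate spline order is rejected."""


def _tps_kernel(r: np.ndarray, order_m: int) -> np.ndarray:
    """Polyharmonic kernel (-1)^m r^(2m-2) log r, continuous (0) at r = 0.

    The (-1)^m factor carries the sign of the conditionally positive
    definite kernel in two dimensions, so the roughness form c^T K c is
    non-negative on the constrained subspace for every order.
    """
    out = np.zeros_like(r)
    pos = r > 0
    rp = r[pos]
    out[pos] = (-1.0) ** order_m * rp ** (2 * order_m - 2) * np.log(rp)
    return out


def _poly_basis(xy: np.ndarray, order_m: int) -> np.ndarray:
    """Monomials x^i y^j with i + j <= m - 1, columns in graded order."""
    x, y = xy[:, 0], xy[:, 1]
    cols = [x ** i * y ** j
            for deg in range(order_m)
            for i in range(deg + 1)
            for j in [deg - i]]
    return np.column_stack(cols)


@dataclass
class SplineDiagnostics:
    """ANUSPLIN-style fit statistics.

    ``signal``/``error_df``/``snr``/``star_flag`` are always present;
    the residual statistics are None when the diagnostics were assembled
    from a published log rather than an in-memory fit.
    """

    signal: float
    error_df: float
    snr: float
    star_flag: bool = False
    msr: float | None = None
    var: float | None = None
    gcv: float | None = None

    @property
    def rtgcv(self) -> float | None:
        return None if self.gcv is None else math.sqrt(self.gcv)

    @property
    def rtmsr(self) -> float | None:
        return None if self.msr is None else math.sqrt(self.msr)

    @property
    def rtvar(self) -> float | None:
        return None if self.var is None else math.sqrt(self.var)


class SplineDesign:
    """Precomputed basis matrices for one data set and spline order.

    Duplicate coordinates are averaged before assembly (the bordered system
    is singular otherwise); the weight of a collapsed group is w / sqrt(n),
    the standard error of the group mean.
    """

    def __init__(self, points, values, covariates=None, order_m: int = 2,
                 weights=None):
        if order_m not in NULL_SPACE_DIM:
            raise ValueError("order_m must be 2, 3 or 4")
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        z = np.asarray(values, dtype=float)
        cov = (np.zeros((len(pts), 0)) if covariates is None
               else np.atleast_2d(np.asarray(covariates, dtype=float)))
        if cov.ndim == 2 and cov.shape[0] != len(pts):
            cov = cov.T
        if cov.ndim == 1:
            cov = cov[:, None]
        w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)

        pts, z, cov, w = _average_duplicates(pts, z, cov, w)
        n = len(pts)
        n_poly = NULL_SPACE_DIM[order_m]
        if n <= n_poly + cov.shape[1]:
            raise SplineFitError(
                f"need more than {n_poly + cov.shape[1]} distinct points "
                f"for order {order_m}")

        # standardise coordinates (centre, joint-range scale) and covariates
        self._xy_centre = pts.mean(axis=0)
        rng = float(np.ptp(pts, axis=0).max())
        self._xy_scale = rng if rng > 0 else 1.0
        self._cov_centre = cov.mean(axis=0) if cov.size else np.zeros(0)
        cov_sd = cov.std(axis=0) if cov.size else np.zeros(0)
        self._cov_scale = np.where(cov_sd > 0, cov_sd, 1.0)

        self.order_m = order_m
        self.points = pts
        self.values = z
        self.covariates = cov
        self.weights = w
        self._u = (pts - self._xy_centre) / self._xy_scale
        self._cov_std = ((cov - self._cov_centre) / self._cov_scale
                         if cov.size else cov)
        r = scipy.linalg.norm(self._u[:, None, :] - self._u[None, :, :], axis=2)
        self.K = _tps_kernel(r, order_m)
        self.T = np.hstack([_poly_basis(self._u, order_m), self._cov_std])
        rank = np.linalg.matrix_rank(self.T)
        if rank < self.T.shape[1]:
            raise SplineFitError(
                "null-space/covariate design is rank deficient "
                "(points collinear or covariate constant)")
        self.n = n
        self.W2 = np.diag(w ** 2)

    def standardise(self, points, covariates=None):
        u = (np.asarray(points, float) - self._xy_centre) / self._xy_scale
        if self.covariates.shape[1] == 0:
            return u, np.zeros((len(u), 0))
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(u):
            cov = cov.T
        return u, (cov - self._cov_centre) / self._cov_scale

    # ------------------------------------------------------------------
    def solve(self, p: float):
        """Solve the bordered system for smoothing parameter p.

        Returns (c, d, z_hat). Stationarity of the penalised criterion under
        the side condition T^T c = 0 gives (K + p W^2) c + T d = z, and the
        residual identity z - z_hat = p W^2 c.
        """
        n, k = self.n, self.T.shape[1]
        M = np.zeros((n + k, n + k))
        M[:n, :n] = self.K + p * self.W2
        M[:n, n:] = self.T
        M[n:, :n] = self.T.T
        rhs = np.concatenate([self.values, np.zeros(k)])
        try:
            sol = scipy.linalg.solve(M, rhs)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise SplineFitError(f"singular spline system: {exc}") from exc
        c, d = sol[:n], sol[n:]
        z_hat = self.values - p * self.weights ** 2 * c
        return c, d, z_hat

    def influence_trace(self, p: float) -> float:
        """tr(A) via the top-left block C of the bordered-system inverse:
        A = I - p W^2 C."""
        n, k = self.n, self.T.shape[1]
        M = np.zeros((n + k, n + k))
        M[:n, :n] = self.K + p * self.W2
        M[:n, n:] = self.T
        M[n:, :n] = self.T.T
        Minv = scipy.linalg.inv(M)
        self._last_C_diag = np.diag(Minv)[:self.n]
        tr = self.n - p * float(np.sum(self.weights ** 2 * self._last_C_diag))
        # A has k unit eigenvalues (unpenalized columns) and the rest in
        # [0, 1], so tr(A) must lie in [k, N]; an excursion means the system
        # is too ill-conditioned at this smoothing parameter to be trusted
        if not k - 1e-3 <= tr <= self.n * (1 + 1e-6):
            raise SplineFitError(
                f"influence trace {tr:.3g} outside [{k}, N]: system "
                f"ill-conditioned at p={p:.3g}")
        return min(tr, float(self.n))

    def influence_diag(self, p: float) -> np.ndarray:
        """Diagonal of the influence matrix A at smoothing parameter p."""
        self.influence_trace(p)
        return 1.0 - p * self.weights ** 2 * self._last_C_diag


def _average_duplicates(pts, z, cov, w):
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True,
                                   return_counts=True)
    if np.all(counts == 1):
        return pts, z, cov, w
    n_groups = counts.size
    pts_o = np.zeros((n_groups, 2))
    z_o = np.zeros(n_groups)
    cov_o = np.zeros((n_groups, cov.shape[1]))
    w_o = np.zeros(n_groups)
    for g in range(n_groups):
        sel = inverse == g
        pts_o[g] = pts[sel][0]
        z_o[g] = z[sel].mean()
        cov_o[g] = cov[sel].mean(axis=0)
        w_o[g] = w[sel].mean() / math.sqrt(sel.sum())
    return pts_o, z_o, cov_o, w_o


def gcv_at(design: SplineDesign, p: float) -> float:
    """Generalized cross-validation score at smoothing parameter p."""
    if p <= 0:
        raise ValueError("p must be positive")
    c, _, _ = design.solve(p)
    tr_a = design.influence_trace(p)
    err_df = design.n - tr_a
    if err_df <= 0:
        raise ZeroDivisionError("tr(I - A) = 0: GCV undefined")
    msr = float(np.sum((p * design.weights * c) ** 2)) / design.n
    return msr / (err_df / design.n) ** 2


@dataclass
class SplineFit:
    """Fitted partial thin-plate spline (all coefficients in the
    standardised coordinate frame held by ``design``)."""

    design: SplineDesign
    p_smooth: float
    coef_rbf: np.ndarray
    coef_poly: np.ndarray
    coef_cov: np.ndarray
    fitted: np.ndarray
    star_flag: bool = False
    _trace_cache: float | None = None

    @property
    def order_m(self) -> int:
        return self.design.order_m

    @property
    def n_obs(self) -> int:
        return self.design.n

    @property
    def trace_A(self) -> float:
        """tr(A), computed lazily (prediction-only uses never need it)."""
        if self._trace_cache is None:
            self._trace_cache = self.design.influence_trace(self.p_smooth)
        return self._trace_cache


_GOLDEN = (math.sqrt(5) - 1) / 2


def _gcv_search(design: SplineDesign, lo: float = 1e-8, hi: float = 1e4,
                n_grid: int = 17, rel_tol: float = 1e-3):
    """Minimise GCV over a log-spaced bracket refined by golden section.

    Returns (p_opt, star_flag); a minimum pinned to the bracket boundary sets
    the failure flag (no interior optimum found).
    """
    def score(p):
        # p small enough to interpolate exactly has no GCV (error df ~ 0);
        # ill-conditioned systems are likewise excluded from the bracket
        try:
            return gcv_at(design, p)
        except (ZeroDivisionError, SplineFitError):
            return math.inf

    grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
    scores = np.array([score(p) for p in grid])
    if not np.isfinite(scores).any():
        return float(grid[-1]), True
    i = int(np.argmin(scores))
    if i in (0, n_grid - 1):
        return float(grid[i]), True
    a, b = math.log10(grid[i - 1]), math.log10(grid[i + 1])
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = score(10 ** x1), score(10 ** x2)
    while (b - a) > rel_tol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = score(10 ** x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = score(10 ** x2)
    return float(10 ** ((a + b) / 2)), False


def fit_partial_spline(points, values, covariates=None, order_m: int = 2,
                       weights=None, smoothing="gcv") -> SplineFit:
    """Fit a partial thin-plate smoothing spline.

    ``smoothing`` is either a fixed positive p or ``"gcv"`` to minimise the
    GCV score over a log-spaced bracket refined by golden-section search.
    """
    design = SplineDesign(points, values, covariates, order_m, weights)
    if smoothing == "gcv":
        p, star = _gcv_search(design)
    else:
        p = float(smoothing)
        if p < 0:
            raise ValueError("smoothing parameter must be non-negative")
        p = max(p, 1e-14)  # p = 0 solved at a tiny ridge for stability
        star = False
    c, d, z_hat = design.solve(p)
    n_poly = NULL_SPACE_DIM[order_m]
    return SplineFit(
        design=design, p_smooth=p, coef_rbf=c,
        coef_poly=d[:n_poly], coef_cov=d[n_poly:],
        fitted=z_hat, star_flag=star)


def predict(fit: SplineFit, locations, covariate_values=None) -> np.ndarray:
    """Evaluate the fitted surface f(x) + b^T y at new locations."""
    des = fit.design
    if des.covariates.shape[1] > 0 and covariate_values is None:
        raise ValueError("covariate values required for prediction")
    u, cov_std = des.standardise(locations, covariate_values)
    r = scipy.linalg.norm(u[:, None, :] - des._u[None, :, :], axis=2)
    out = _tps_kernel(r, des.order_m) @ fit.coef_rbf
    out += _poly_basis(u, des.order_m) @ fit.coef_poly
    if cov_std.shape[1]:
        out += cov_std @ fit.coef_cov
    return out


def diagnostics(fit: SplineFit) -> SplineDiagnostics:
    """ANUSPLIN-style statistics of a fit; raises if the error degrees of
    freedom vanish (perfect interpolation has no residual variance)."""
    des = fit.design
    n = des.n
    signal = fit.trace_A
    error_df = n - signal
    if error_df <= 1e-8 * n:
        raise ZeroDivisionError("error degrees of freedom ~ 0: SNR undefined")
    resid_w = (des.values - fit.fitted) / des.weights
    wrss = float(np.sum(resid_w ** 2))
    msr = wrss / n
    var = wrss / error_df
    gcv = msr / (error_df / n) ** 2
    return SplineDiagnostics(signal=signal, error_df=error_df,
                             snr=signal / error_df, star_flag=fit.star_flag,
                             msr=msr, var=var, gcv=gcv)


def select_spline_order(candidates, n_obs: int) -> int:
    """Pick the spline order from per-order diagnostics.

    Candidates are (order, SplineDiagnostics) pairs. Rows carrying the
    failure flag or with Signal >= n_obs / 2 (surface too complex for the
    data) are discarded; among the rest the order with minimal SNR wins,
    ties going to the lowest order.
    """
    admissible = [(order, diag) for order, diag in candidates
                  if not diag.star_flag and diag.signal < n_obs / 2]
    if not admissible:
        raise OrderSelectionError("every candidate order was rejected")
    return min(admissible, key=lambda od: (od[1].snr, od[0]))[0]


def rasterize(fit: SplineFit, dem) -> "GridSurface":
    """Evaluate the fitted surface at every DEM cell centre, with the DEM
    value as covariate; nodata cells propagate."""
    from .grids import GridSurface  # local import to avoid cycle

    mask = dem.mask()
    if not mask.any():
        raise ValueError("DEM is entirely nodata")
    gx, gy = dem.cell_centres()
    locs = np.column_stack([gx[mask], gy[mask]])
    cov = dem.values[mask][:, None] if fit.design.covariates.shape[1] else None
    vals = predict(fit, locs, cov)
    out = np.full(dem.values.shape, dem.nodata, dtype=float)
    out[mask] = vals
    return GridSurface(dem.x_origin, dem.y_origin, dem.cell_size, out,
                       nodata=dem.nodata)
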