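"""Partial thin-plate spline: oracles, limits, diagnostics, selection."""

import numpy as np
import pytest

from bamboocarbon import tps
from bamboocarbon.datasets import SELECTED_ORDERS, spline_candidates
from bamboocarbon.grids import NODATA, GridSurface
from bamboocarbon.scene import SceneConfig, generate_dem, generate_truth_fields
from bamboocarbon.tps import (OrderSelectionError, SplineDesign,
                              SplineDiagnostics, diagnostics,
                              fit_partial_spline, gcv_at, predict, rasterize,
                              select_spline_order)


def _random_design(rng, n=20, m=2, with_cov=True):
    pts = rng.uniform(0, 100, (n, 2))
    cov = rng.normal(800, 120, n) if with_cov else None
    z = (1 + 0.04 * pts[:, 0] - 0.02 * pts[:, 1]
         + (0.001 * cov if with_cov else 0) + rng.normal(0, 0.3, n))
    return pts, z, cov


def _explicit_influence_matrix(pts, cov, m, p):
    """Independent oracle: build A column by column by fitting the spline to
    each unit-response vector and reading the fitted values."""
    n = len(pts)
    A = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        _, _, z_hat = SplineDesign(pts, e, cov, m).solve(p)
        A[:, j] = z_hat
    return A


class TestFitOracles:
    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_polynomial_null_space_reproduced_for_any_p(self, rng, m):
        pts = rng.uniform(0, 10, (40, 2))
        z = 5.0 - 2.0 * pts[:, 0] + 1.5 * pts[:, 1]   # total degree 1 < m
        for p in (1e-4, 1.0, 1e3):
            fit = fit_partial_spline(pts, z, None, order_m=m, smoothing=p)
            np.testing.assert_allclose(fit.fitted, z, atol=1e-8 * np.ptp(z))

    def test_interpolation_limit_as_p_to_zero(self, rng):
        pts, z, cov = _random_design(rng)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=1e-12)
        assert np.abs(fit.fitted - z).max() < 1e-6 * np.ptp(z)

    @pytest.mark.parametrize("m,n", [(2, 20), (3, 25), (4, 30)])
    def test_matches_explicit_influence_matrix(self, rng, m, n):
        pts, z, cov = _random_design(rng, n=n)
        p = 0.05
        fit = fit_partial_spline(pts, z, cov, order_m=m, smoothing=p)
        A = _explicit_influence_matrix(pts, cov, m, p)
        np.testing.assert_allclose(fit.fitted, A @ z, atol=1e-7 * np.ptp(z))
        assert fit.trace_A == pytest.approx(np.trace(A), abs=1e-6)

    def test_side_conditions_hold(self, rng):
        pts, z, cov = _random_design(rng, n=30)
        fit = fit_partial_spline(pts, z, cov, order_m=3, smoothing=0.1)
        constraint = fit.design.T.T @ fit.coef_rbf
        scale = np.abs(fit.coef_rbf).max()
        assert np.abs(constraint).max() < 1e-8 * max(scale, 1.0)

    def test_residual_norm_nondecreasing_in_p(self, rng):
        pts, z, cov = _random_design(rng, n=30)
        norms = []
        for p in np.logspace(-6, 4, 9):
            fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=p)
            norms.append(np.linalg.norm(z - fit.fitted))
        assert np.all(np.diff(norms) >= -1e-9)

    def test_large_p_approaches_polynomial_plus_covariate_regression(self, rng):
        pts, z, cov = _random_design(rng, n=40)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=1e9)
        X = np.column_stack([np.ones(40), pts, cov])
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        np.testing.assert_allclose(fit.fitted, X @ beta, rtol=1e-4)

    def test_duplicate_points_averaged(self, rng):
        pts = np.vstack([[0, 0], [0, 0], [10, 0], [0, 10], [10, 10],
                         rng.uniform(0, 10, (6, 2))])
        z = rng.normal(0, 1, 11)
        fit = fit_partial_spline(pts, z, None, order_m=2, smoothing=1.0)
        assert fit.n_obs == 10  # the duplicate pair collapsed

    def test_insufficient_points_rejected(self, rng):
        pts = rng.uniform(0, 1, (3, 2))
        with pytest.raises(tps.SplineFitError):
            fit_partial_spline(pts, np.zeros(3), None, order_m=4,
                               smoothing=1.0)


class TestGcv:
    def test_zero_residuals_zero_gcv(self, rng):
        pts = rng.uniform(0, 10, (15, 2))
        z = 1.0 + 2.0 * pts[:, 0]
        design = SplineDesign(pts, z, None, 2)
        assert gcv_at(design, 1.0) == pytest.approx(0.0, abs=1e-16)

    def test_brute_force_equivalence_at_n8(self, rng):
        pts, z, _ = _random_design(rng, n=8, with_cov=False)
        design = SplineDesign(pts, z, None, 2)
        p = 0.2
        A = _explicit_influence_matrix(pts, None, 2, p)
        resid = (np.eye(8) - A) @ z
        brute = (resid @ resid / 8) / (np.trace(np.eye(8) - A) / 8) ** 2
        assert gcv_at(design, p) == pytest.approx(brute, rel=1e-8)

    def test_unit_weight_identity_with_msr(self, rng):
        # GCV = MSR / (error_df/N)^2 when all weights are one
        pts, z, cov = _random_design(rng, n=25)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=0.5)
        d = diagnostics(fit)
        assert d.gcv == pytest.approx(d.msr / (d.error_df / fit.n_obs) ** 2)
        assert gcv_at(fit.design, 0.5) == pytest.approx(d.gcv, rel=1e-8)

    def test_gcv_selection_near_dense_grid_optimum(self, rng):
        # held-out error of the GCV-chosen p within 1.2x the best dense-grid p
        cfg = SceneConfig(extent=(0, 0, 1000, 1000), n_tracks=7,
                          along_track_spacing=60.0, seed=5)
        truth = generate_truth_fields(generate_dem(cfg), cfg)
        from bamboocarbon.scene import sample_footprints
        fp = sample_footprints(truth, cfg)
        pts = fp[["x", "y"]].to_numpy()
        z = fp["pai"].to_numpy()
        elev = fp["elevation"].to_numpy()
        gx, gy = truth.dem.cell_centres()
        locs = np.column_stack([gx.ravel(), gy.ravel()])
        dem_cov = truth.dem.values.ravel()[:, None]
        true_vals = truth.parameter_fields["pai"].values.ravel()

        def held_out_rmse(p):
            fit = fit_partial_spline(pts, z, elev, order_m=2, smoothing=p)
            return np.sqrt(np.mean((predict(fit, locs, dem_cov)
                                    - true_vals) ** 2))

        fit = fit_partial_spline(pts, z, elev, order_m=2, smoothing="gcv")
        rmse_gcv = held_out_rmse(fit.p_smooth)
        best = min(held_out_rmse(p) for p in np.logspace(-6, 3, 19))
        assert rmse_gcv <= 1.2 * best


class TestDiagnostics:
    @pytest.mark.parametrize("m,smoothing", [
        (2, "gcv"), (2, 0.01), (3, 1.0), (4, 10.0)])
    def test_signal_error_sum_to_n(self, rng, m, smoothing):
        for _ in range(2):
            pts, z, cov = _random_design(rng, n=30)
            fit = fit_partial_spline(pts, z, cov, order_m=m,
                                     smoothing=smoothing)
            d = diagnostics(fit)
            assert d.signal + d.error_df == pytest.approx(fit.n_obs,
                                                          abs=1e-8 * 30)
            assert d.snr == pytest.approx(d.signal / d.error_df)
            assert d.rtgcv == pytest.approx(np.sqrt(d.gcv))
            assert d.rtmsr == pytest.approx(np.sqrt(d.msr))
            assert d.rtvar == pytest.approx(np.sqrt(d.var))

    @pytest.mark.parametrize("signal,error,expected", [
        (97.5, 2258.5, 0.043),    # canopy-cover candidate, order 2
        (91.9, 2337.1, 0.039),    # toc_roughness candidate, order 4
        (4.6, 2351.4, 0.002),     # elevation candidate, order 2
    ])
    def test_snr_reproduces_published_cells(self, signal, error, expected):
        d = SplineDiagnostics(signal=signal, error_df=error,
                              snr=signal / error)
        assert round(d.snr, 3) == expected

    def test_perfect_interpolation_signalled(self, rng):
        pts, z, cov = _random_design(rng, n=15)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=1e-13)
        with pytest.raises(ZeroDivisionError):
            diagnostics(fit)


class TestOrderSelection:
    @pytest.mark.parametrize("variable", sorted(SELECTED_ORDERS))
    def test_published_rows_reproduce_selected_degrees(self, variable):
        cands, n_obs = spline_candidates(variable)
        assert select_spline_order(cands, n_obs) == SELECTED_ORDERS[variable]

    def test_starred_candidate_discarded(self):
        cands = [(2, SplineDiagnostics(10, 90, 0.9, star_flag=True)),
                 (3, SplineDiagnostics(10, 90, 0.5))]
        assert select_spline_order(cands, 100) == 3

    def test_signal_over_half_discarded(self):
        cands = [(2, SplineDiagnostics(60, 40, 0.01)),
                 (3, SplineDiagnostics(10, 90, 0.5))]
        assert select_spline_order(cands, 100) == 3

    def test_tie_goes_to_lowest_order(self):
        cands = [(4, SplineDiagnostics(10, 90, 0.1)),
                 (2, SplineDiagnostics(10, 90, 0.1))]
        assert select_spline_order(cands, 100) == 2

    def test_all_discarded_raises(self):
        with pytest.raises(OrderSelectionError):
            select_spline_order(
                [(2, SplineDiagnostics(60, 40, 0.1))], 100)


class TestPredictRasterize:
    def test_training_locations_return_fitted_values(self, rng):
        pts, z, cov = _random_design(rng, n=25)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=0.3)
        np.testing.assert_allclose(predict(fit, pts, cov), fit.fitted,
                                   atol=1e-9)

    def test_constant_data_predicts_constant(self, rng):
        pts = rng.uniform(0, 10, (15, 2))
        fit = fit_partial_spline(pts, np.full(15, 7.0), None, order_m=2,
                                 smoothing=1.0)
        out = predict(fit, rng.uniform(0, 10, (8, 2)))
        np.testing.assert_allclose(out, 7.0, atol=1e-8)

    def test_missing_covariate_rejected(self, rng):
        pts, z, cov = _random_design(rng)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=0.3)
        with pytest.raises(ValueError):
            predict(fit, pts[:2])

    def test_held_out_rmse_below_nugget(self):
        cfg = SceneConfig(extent=(0, 0, 1500, 1500), n_tracks=8,
                          along_track_spacing=70.0, seed=3)
        truth = generate_truth_fields(generate_dem(cfg), cfg)
        from bamboocarbon.scene import sample_footprints
        fp = sample_footprints(truth, cfg)
        fit = fit_partial_spline(fp[["x", "y"]].to_numpy(),
                                 fp["h_canopy_abs"].to_numpy(),
                                 fp["elevation"].to_numpy(),
                                 order_m=2, smoothing="gcv")
        rng = np.random.default_rng(0)
        xs = rng.uniform(100, 1400, 5)
        ys = rng.uniform(100, 1400, 5)
        pred = predict(fit, np.column_stack([xs, ys]),
                       truth.dem.sample_bilinear(xs, ys)[:, None])
        true = truth.parameter_fields["h_canopy_abs"].sample_bilinear(xs, ys)
        rmse = np.sqrt(np.mean((pred - true) ** 2))
        assert rmse < cfg.parameters["h_canopy_abs"].nugget_sd

    def test_rasterize_matches_cell_by_cell_predict(self, rng):
        pts, z, cov = _random_design(rng, n=20)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=0.3)
        dem = GridSurface(0.0, 50.0, 10.0, rng.normal(800, 50, (5, 5)))
        dem.values[1, 2] = NODATA
        grid = rasterize(fit, dem)
        for r in range(5):
            for c in range(5):
                x = 5.0 + 10.0 * c
                y = 50.0 - 5.0 - 10.0 * r
                if (r, c) == (1, 2):
                    assert grid.values[r, c] == NODATA
                else:
                    expected = predict(fit, [[x, y]],
                                       [[dem.values[r, c]]])[0]
                    assert grid.values[r, c] == pytest.approx(expected)

    def test_single_cell_grid(self, rng):
        pts, z, cov = _random_design(rng, n=20)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=0.3)
        dem = GridSurface(0.0, 10.0, 10.0, np.array([[750.0]]))
        grid = rasterize(fit, dem)
        assert grid.values[0, 0] == pytest.approx(
            predict(fit, [[5.0, 5.0]], [[750.0]])[0])

    def test_all_nodata_dem_rejected(self, rng):
        pts, z, cov = _random_design(rng)
        fit = fit_partial_spline(pts, z, cov, order_m=2, smoothing=0.3)
        dem = GridSurface(0.0, 10.0, 10.0, np.full((2, 2), NODATA))
        with pytest.raises(ValueError):
            rasterize(fit, dem)
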