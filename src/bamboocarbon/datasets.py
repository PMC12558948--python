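"""Published reference tables for the nine spaceborne-LiDAR predictors.

These are the printed campaign results for *Dendrocalamus giganteus* stands
in Xinping County (Yunnan): ANUSPLIN-style spline diagnostics per candidate
order, GCV summary statistics, fitted variogram parameters, interpolation
cross-validation metrics, and the regression-model scores. They serve as
inputs for arithmetic checks (the raw footprint and plot data are not
public) — e.g. re-running the order-selection rule on the printed
diagnostic rows, or verifying nugget-ratio and accuracy-metric identities.
"""

from __future__ import annotations

import pandas as pd

from .tps import SplineDiagnostics

#: (population size, sampling interval, selected count) per sensor family
FOOTPRINT_COUNTS = {
    "GEDI": (57_217, 24, 2_384),
    "ATLAS": (21_080, 9, 2_342),
}

#: plot AGC summary over the 51 field plots: (min, max, mean, sd) in Mg/ha
PLOT_AGC_SUMMARY = (4.08, 101.78, 41.63, 20.55)

#: spline diagnostics per variable and candidate order:
#: (order, error_df, signal, snr_printed, starred)
SPLINE_DIAGNOSTICS = {
    "cover": [(2, 2258.5, 97.5, 0.043, False),
              (3, 2258.5, 97.5, 0.043, False),
              (4, 2266.8, 89.2, 0.039, False)],
    "digital_elevation_model": [(2, 2351.4, 4.6, 0.002, False),
                                (3, 2349.0, 7.0, 0.003, True),
                                (4, 2343.1, 12.9, 0.006, False)],
    "pai": [(2, 2018.5, 337.5, 0.167, False),
            (3, 2106.7, 249.3, 0.118, False),
            (4, 2251.4, 104.6, 0.046, False)],
    "sensitivity": [(2, 2042.1, 313.9, 0.154, False),
                    (3, 2092.9, 263.1, 0.126, False),
                    (4, 2104.8, 251.2, 0.119, False)],
    "toc_roughness": [(2, 2301.1, 127.9, 0.056, False),
                      (3, 2329.0, 100.0, 0.043, False),
                      (4, 2337.1, 91.9, 0.039, False)],
    "h_median_canopy_abs": [(2, 1012.3, 1416.7, 1.399, False),
                            (3, 1596.5, 832.5, 0.521, False),
                            (4, 2329.5, 99.5, 0.043, False)],
    "asr": [(2, 1831.8, 554.2, 3.305, False),
            (3, 2129.1, 256.9, 8.288, False),
            (4, 2151.1, 234.9, 9.158, False)],
    "h_canopy_abs": [(2, 1033.6, 1395.4, 1.350, False),
                     (3, 1608.8, 820.2, 0.510, False),
                     (4, 2333.1, 95.9, 0.041, False)],
    "h_max_canopy_abs": [(2, 1035.1, 1393.9, 1.347, False),
                         (3, 1612.9, 816.1, 0.510, False),
                         (4, 2333.8, 95.2, 0.041, False)],
}

#: published optimal spline degree per variable
SELECTED_ORDERS = {
    "cover": 4, "pai": 4, "sensitivity": 4, "digital_elevation_model": 2,
    "toc_roughness": 4, "h_median_canopy_abs": 4, "asr": 2,
    "h_canopy_abs": 4, "h_max_canopy_abs": 4,
}

#: GCV summary per variable: (gcv, msr, var, rtgcv, rtmsr, rtvar)
GCV_SUMMARY = {
    "cover": (0.09, 0.08, 0.09, 0.30, 0.29, 0.30),
    "digital_elevation_model": (183.00, 183.00, 183.00, 13.50, 13.50, 13.50),
    "pai": (3.47, 3.16, 3.31, 1.86, 1.78, 1.82),
    "sensitivity": (0.00, 0.00, 0.00, 0.02, 0.02, 0.02),
    "toc_roughness": (0.11, 0.10, 0.10, 0.33, 0.32, 0.32),
    "h_median_canopy_abs": (0.15, 0.140, 0.140, 0.39, 0.38, 0.38),
    "asr": (0.00, 0.00, 0.00, 0.07, 0.05, 0.06),
    "h_canopy_abs": (0.148, 0.137, 0.142, 0.385, 0.370, 0.377),
    "h_max_canopy_abs": (0.148, 0.136, 0.142, 0.384, 0.369, 0.377),
}

#: fitted variogram parameters: variable -> model -> (C0, sill, ratio_pct,
#: range_m, rss, r2); ratio is the printed 100*C0/(C0+C) cell
VARIOGRAM_FITS = {
    "cover": {"Gaussian": (0.1, 53.71, 0.19, 12817.18, 715.0, 0.82),
              "Spherical": (0.1, 53.52, 0.19, 16100.0, 777.0, 0.81),
              "Exponential": (0.1, 53.87, 0.19, 18900.0, 1226.0, 0.71)},
    "toc_roughness": {"Gaussian": (6.67, 19.33, 34.50, 19572.17, 78.50, 0.726),
                      "Spherical": (5.04, 19.46, 25.90, 25200.0, 72.3, 0.748),
                      "Exponential": (0.01, 19.37, 0.05, 20700.0, 74.4, 0.740)},
    "h_median_canopy_abs": {
        "Gaussian": (103.0, 775.5, 13.28, 24941.53, 40386.0, 0.94),
        "Spherical": (15.0, 776.8, 1.93, 30400.0, 35443.0, 0.95),
        "Exponential": (1.0, 804.3, 0.12, 37800.0, 77303.0, 0.90)},
}

#: regression-model scores: family -> (r2, rmse Mg/ha, p_pct, rrmse_pct)
MODEL_SCORES = {
    "xgboost": (0.93, 5.89, 85.84, 14.16),
    "lightgbm": (0.52, 14.61, 64.84, 35.16),
    "rfr": (0.90, 8.23, 79.79, 20.21),
}

#: county-wide mapped AGC: (mean, min, max) Mg/ha and total stock Mg
MAPPED_AGC = {"mean": 40.62, "min": 15.70, "max": 81.96, "total": 1.14e7}


def spline_candidates(variable: str):
    """(order, SplineDiagnostics) candidates for one variable, plus the
    observation count N = Signal + Error (constant across orders)."""
    rows = SPLINE_DIAGNOSTICS[variable]
    cands = [(order, SplineDiagnostics(signal=signal, error_df=error,
                                       snr=snr, star_flag=star))
             for order, error, signal, snr, star in rows]
    n_obs = rows[0][1] + rows[0][2]
    return cands, n_obs


def spline_diagnostics_frame() -> pd.DataFrame:
    rows = []
    for variable, entries in SPLINE_DIAGNOSTICS.items():
        for order, error, signal, snr, star in entries:
            rows.append({"variable": variable, "order": order,
                         "error_df": error, "signal": signal, "snr": snr,
                         "star": star})
    return pd.DataFrame(rows)
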