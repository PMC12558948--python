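"""Allometric above-ground biomass and carbon for *Dendrocalamus giganteus*.

Per-culm biomass follows power-law allometry ``w = a * DBH**b`` fitted
separately for culm (stalk), branch and leaf components, with DBH in cm and
biomass in kg per culm. Component biomass converts to carbon with
component-specific carbon fractions (0.45 culm, 0.45 branch, 0.43 leaf).
Plot-level above-ground carbon (AGC) density aggregates culm carbon over the
plot and normalises by plot area, reported in Mg/ha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AllometryCoefficients:
    """Power-law coefficients (a, b) per component and carbon fractions."""

    culm: tuple[float, float] = (0.145, 2.4197)
    branch: tuple[float, float] = (0.0224, 2.5286)
    leaf: tuple[float, float] = (0.0196, 1.917)
    carbon_fraction: dict = field(
        default_factory=lambda: {"culm": 0.45, "branch": 0.45, "leaf": 0.43})

    def __post_init__(self):
        for a, b in (self.culm, self.branch, self.leaf):
            if a <= 0 or b <= 0:
                raise ValueError("allometric coefficients must be positive")
        for fc in self.carbon_fraction.values():
            if not 0 < fc <= 1:
                raise ValueError("carbon fractions must lie in (0, 1]")


DEFAULT_COEFFS = AllometryCoefficients()


def culm_biomass(dbh: float, coeffs: AllometryCoefficients = DEFAULT_COEFFS
                 ) -> tuple[float, float, float]:
    """Component biomass (culm, branch, leaf) in kg for one culm of given DBH (cm)."""
    if dbh < 0:
        raise ValueError("DBH must be non-negative")
    return (
        coeffs.culm[0] * dbh ** coeffs.culm[1],
        coeffs.branch[0] * dbh ** coeffs.branch[1],
        coeffs.leaf[0] * dbh ** coeffs.leaf[1],
    )


def culm_carbon(dbh: float, coeffs: AllometryCoefficients = DEFAULT_COEFFS) -> float:
    """Above-ground carbon (kg C) of one culm: component biomass x carbon fraction."""
    w_culm, w_branch, w_leaf = culm_biomass(dbh, coeffs)
    fc = coeffs.carbon_fraction
    return fc["culm"] * w_culm + fc["branch"] * w_branch + fc["leaf"] * w_leaf


def plot_area(radius_m: float, pi_decimals: int | None = None) -> float:
    """Circular plot area in m².

    ``pi_decimals`` rounds pi before squaring, reproducing inventory-sheet
    conventions (radius 12.5 m with pi = 3.14 gives the commonly printed
    490.63 m²); ``None`` uses full precision.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    pi = math.pi if pi_decimals is None else round(math.pi, pi_decimals)
    return pi * radius_m ** 2


def plot_agc_density(dbh_list: Iterable[float], area_m2: float,
                     coeffs: AllometryCoefficients = DEFAULT_COEFFS,
                     mean_tree: bool = False) -> float:
    """Plot AGC density in Mg/ha from a per-culm DBH list and plot area.

    With ``mean_tree=True`` the plot is represented by one culm of quadratic
    mean DBH whose carbon is scaled by the culm count (the "representative
    mean tree" inventory shortcut); default sums carbon over the full list.
    """
    if area_m2 <= 0:
        raise ValueError("plot area must be positive")
    dbh = np.asarray(list(dbh_list), dtype=float)
    if dbh.size == 0:
        return 0.0
    if np.any(dbh < 0):
        raise ValueError("DBH must be non-negative")
    if mean_tree:
        dq = float(np.sqrt(np.mean(dbh ** 2)))
        total_kg = dbh.size * culm_carbon(dq, coeffs)
    else:
        total_kg = float(sum(culm_carbon(d, coeffs) for d in dbh))
    return (total_kg / 1000.0) / (area_m2 / 10000.0)


def summarize_agc(plots: pd.DataFrame, column: str = "agc_mg_ha"
                  ) -> tuple[float, float, float, float]:
    """(min, max, mean, sd) of plot AGC in Mg/ha; sd uses the n-1 denominator.

    A single plot reports sd = 0.0 (documented convention).
    """
    if len(plots) == 0:
        raise ValueError("plot table is empty")
    v = plots[column].to_numpy(dtype=float)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(v.min()), float(v.max()), float(v.mean()), sd


def plots_from_dbh(records: Sequence[dict],
                   coeffs: AllometryCoefficients = DEFAULT_COEFFS,
                   pi_decimals: int | None = None) -> pd.DataFrame:
    """Build a plot table (plot_id, x, y, radius_m, dbh_list, agc_mg_ha).

    Each record needs plot_id, x, y, radius_m and a dbh_list of cm values;
    AGC density is computed here so the table is self-consistent.
    """
    rows = []
    for rec in records:
        area = plot_area(rec["radius_m"], pi_decimals)
        agc = plot_agc_density(rec["dbh_list"], area, coeffs)
        rows.append({
            "plot_id": rec["plot_id"], "x": rec["x"], "y": rec["y"],
            "radius_m": rec["radius_m"],
            "dbh_list": ";".join(f"{d:.3f}" for d in rec["dbh_list"]),
            "agc_mg_ha": agc,
        })
    return pd.DataFrame(rows, columns=["plot_id", "x", "y", "radius_m",
                                       "dbh_list", "agc_mg_ha"])
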