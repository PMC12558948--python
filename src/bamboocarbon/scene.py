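"""Synthetic study scenes: DEM, parameter truth fields, footprints, plots.

Every downstream stage (spline and co-kriging surfaces, cross-validation,
feature selection, carbon mapping) is exercised on scenes generated here, so
the whole pipeline is testable without any satellite download. A scene
emulates the statistical structure the analysis assumes:

* a smooth DEM with configurable relief;
* nine canopy/terrain parameter fields, each a smooth spatial component
  (sum of seeded Gaussian bumps) plus a linear elevation dependence —
  exactly the partial-spline data model — with nugget noise added only at
  footprint sampling;
* footprints arranged along parallel ground tracks, reproducing the striping
  geometry of spaceborne LiDAR;
* circular field plots whose per-culm DBH draws are scaled so allometric
  plot carbon tracks the ground-truth AGC field at the plot centre.

The AGC truth field is a stated linear combination of cover, pai and
h_canopy_abs plus a smooth disturbance, so supervised recovery has a known
target. All outputs are bit-reproducible from the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import allometry
from .grids import GridSurface

#: canonical predictor names (four full-waveform, five photon-counting)
PARAMETER_NAMES = (
    "cover", "digital_elevation_model", "pai", "sensitivity",
    "toc_roughness", "h_median_canopy_abs", "asr",
    "h_canopy_abs", "h_max_canopy_abs",
)

GEDI_PARAMS = PARAMETER_NAMES[:4]
ATLAS_PARAMS = PARAMETER_NAMES[4:]


@dataclass(frozen=True)
class ParameterFieldSpec:
    """Intercept, smooth-component amplitude (1 sd), linear elevation
    coefficient (units per metre of raw elevation) and footprint nugget sd.

    field = intercept + amplitude * smooth(x, y) + elev_coeff * elevation
    """

    intercept: float
    amplitude: float
    elev_coeff: float
    nugget_sd: float


def _default_parameters() -> dict[str, ParameterFieldSpec]:
    # magnitudes follow typical GEDI L2B / ATL08 value ranges over dense
    # subtropical bamboo stands; intercepts assume ~1125 m mean elevation
    return {
        "cover": ParameterFieldSpec(0.49, 0.12, 1.0e-4, 0.03),
        "digital_elevation_model": ParameterFieldSpec(0.0, 0.0, 1.0, 5.0),
        "pai": ParameterFieldSpec(2.40, 0.8, 5.0e-4, 0.15),
        "sensitivity": ParameterFieldSpec(0.94, 0.015, 1.0e-5, 0.004),
        "toc_roughness": ParameterFieldSpec(2.40, 0.9, 5.0e-4, 0.20),
        "h_median_canopy_abs": ParameterFieldSpec(12.75, 3.0, 2.0e-3, 0.50),
        "asr": ParameterFieldSpec(0.28, 0.06, 2.0e-5, 0.010),
        "h_canopy_abs": ParameterFieldSpec(17.75, 4.0, 2.0e-3, 0.50),
        "h_max_canopy_abs": ParameterFieldSpec(21.75, 4.5, 2.0e-3, 0.50),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic scene; the seed fixes every draw."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 2500.0, 2500.0)
    cell_size: float = 25.0
    min_elev: float = 450.0
    max_elev: float = 1800.0
    relief_amplitude: float | None = None  # None -> max_elev - min_elev
    n_bumps: int = 8
    n_tracks: int = 12
    track_azimuth: float = 15.0
    along_track_spacing: float = 60.0
    track_jitter_sd: float = 0.0
    parameters: Mapping[str, ParameterFieldSpec] = field(
        default_factory=_default_parameters)
    agc_coeffs: Mapping[str, float] = field(default_factory=lambda: {
        "intercept": -30.0, "cover": 40.0, "pai": 6.0, "h_canopy_abs": 1.5})
    agc_noise_amplitude: float = 3.0
    n_plots: int = 51
    plot_radius: float = 12.5
    dbh_lognormal: tuple[float, float] = (np.log(12.0), 0.25)
    culm_density: tuple[int, int] = (0, 150)
    seed: int = 0

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent is degenerate")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_tracks < 1:
            raise ValueError("need at least one ground track")
        for name, spec in self.parameters.items():
            if name not in PARAMETER_NAMES:
                raise ValueError(f"unknown parameter field {name!r}")
            if spec.nugget_sd < 0:
                raise ValueError(f"negative nugget sd for {name!r}")


@dataclass
class TruthBundle:
    """Ground-truth rasters of one scene, all on the DEM's grid."""

    dem: GridSurface
    parameter_fields: dict[str, GridSurface]
    agc_field: GridSurface


def _rng(config: SceneConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


def _bump_field(gx: np.ndarray, gy: np.ndarray,
                extent, n_bumps: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian bumps with seeded centres/widths/signs, standardised
    to zero mean and unit sd over the grid (zero if sd is zero)."""
    xmin, ymin, xmax, ymax = extent
    span = max(xmax - xmin, ymax - ymin)
    cx = rng.uniform(xmin, xmax, n_bumps)
    cy = rng.uniform(ymin, ymax, n_bumps)
    width = rng.uniform(0.15, 0.35, n_bumps) * span
    amp = rng.normal(0.0, 1.0, n_bumps)
    f = np.zeros_like(gx)
    for j in range(n_bumps):
        f += amp[j] * np.exp(-((gx - cx[j]) ** 2 + (gy - cy[j]) ** 2)
                             / (2.0 * width[j] ** 2))
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)


def generate_dem(config: SceneConfig) -> GridSurface:
    """Smooth synthetic DEM within [min_elev, max_elev].

    The surface is a standardised bump field plus a mild linear trend,
    rescaled so the relief spans ``relief_amplitude`` metres around the
    mid-elevation (relief 0 gives a constant raster).
    """
    xmin, ymin, xmax, ymax = config.extent
    n_cols = max(int(round((xmax - xmin) / config.cell_size)), 1)
    n_rows = max(int(round((ymax - ymin) / config.cell_size)), 1)
    grid = GridSurface(xmin, ymax, config.cell_size,
                       np.zeros((n_rows, n_cols)))
    gx, gy = grid.cell_centres()
    rng = _rng(config, 0)
    raw = _bump_field(gx, gy, config.extent, config.n_bumps, rng)
    # gentle north-west-up trend so aspect structure exists
    trend = ((gx - gx.mean()) / (xmin - xmax + 1e-12)
             + (gy - gy.mean()) / (ymax - ymin + 1e-12))
    raw = raw + 0.8 * (trend - trend.mean()) / max(trend.std(), 1e-12)
    lo, hi = raw.min(), raw.max()
    unit = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)

    relief = (config.max_elev - config.min_elev
              if config.relief_amplitude is None else config.relief_amplitude)
    centre = 0.5 * (config.min_elev + config.max_elev)
    grid.values = centre + relief * (unit - 0.5)
    return grid


def generate_truth_fields(dem: GridSurface, config: SceneConfig) -> TruthBundle:
    """Nine parameter truth fields plus the AGC field, all noise-free.

    field = intercept + amplitude * smooth(x, y) + elev_coeff * elevation;
    AGC = linear combination of cover, pai and h_canopy_abs plus a smooth
    disturbance, clipped at zero.
    """
    gx, gy = dem.cell_centres()
    fields: dict[str, GridSurface] = {}
    for i, name in enumerate(PARAMETER_NAMES):
        spec = config.parameters.get(name)
        if spec is None:
            continue
        rng = _rng(config, 1, i)
        smooth = (_bump_field(gx, gy, config.extent, config.n_bumps, rng)
                  if spec.amplitude != 0 else np.zeros_like(gx))
        vals = (spec.intercept + spec.amplitude * smooth
                + spec.elev_coeff * dem.values)
        fields[name] = dem.copy_with(vals)

    coeffs = dict(config.agc_coeffs)
    agc = np.full_like(gx, coeffs.pop("intercept", 0.0))
    for name, beta in coeffs.items():
        if name not in fields:
            raise ValueError(f"AGC truth references unknown field {name!r}")
        agc = agc + beta * fields[name].values
    if config.agc_noise_amplitude > 0:
        rng = _rng(config, 2)
        agc = agc + config.agc_noise_amplitude * _bump_field(
            gx, gy, config.extent, config.n_bumps, rng)
    agc_field = dem.copy_with(np.clip(agc, 0.0, None))
    return TruthBundle(dem=dem, parameter_fields=fields, agc_field=agc_field)


def _track_points(config: SceneConfig, rng: np.random.Generator):
    """Footprint coordinates along parallel ground tracks; yields
    (track_index, x, y) for points inside the extent."""
    xmin, ymin, xmax, ymax = config.extent
    cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    az = np.deg2rad(config.track_azimuth)
    along = np.array([np.sin(az), np.cos(az)])      # azimuth from north
    across = np.array([np.cos(az), -np.sin(az)])
    half_diag = 0.5 * np.hypot(xmax - xmin, ymax - ymin)
    span = 2.0 * half_diag
    if config.n_tracks == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-0.45 * span, 0.45 * span, config.n_tracks)
    s_pos = np.arange(0.0, half_diag + 1e-9, config.along_track_spacing)
    s = np.concatenate([-s_pos[:0:-1], s_pos])  # symmetric about track centre
    for ti, off in enumerate(offsets):
        jitter = (rng.normal(0.0, config.track_jitter_sd)
                  if config.track_jitter_sd > 0 else 0.0)
        base = np.array([cx, cy]) + (off + jitter) * across
        pts = base[None, :] + s[:, None] * along[None, :]
        inside = ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
                  & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))
        for x, y in pts[inside]:
            yield ti, x, y


def sample_footprints(truth: TruthBundle, config: SceneConfig) -> pd.DataFrame:
    """Footprint table: truth values at track positions plus nugget noise.

    Tracks alternate sensor families (even index GEDI, odd ATLAS); every
    record carries all parameter values, the DEM elevation at its location
    and a unit quality flag.
    """
    rng = _rng(config, 3)
    rows = [(ti, x, y) for ti, x, y in _track_points(config, rng)]
    if not rows:
        raise ValueError("no footprints fall inside the extent")
    track = np.array([r[0] for r in rows])
    xs = np.array([r[1] for r in rows])
    ys = np.array([r[2] for r in rows])

    table = pd.DataFrame({
        "record_id": np.arange(len(rows)),
        "sensor": np.where(track % 2 == 0, "GEDI", "ATLAS"),
        "x": xs, "y": ys,
        "elevation": truth.dem.sample_bilinear(xs, ys),
    })
    for name, grid in truth.parameter_fields.items():
        spec = config.parameters[name]
        vals = grid.sample_bilinear(xs, ys)
        if spec.nugget_sd > 0:
            vals = vals + rng.normal(0.0, spec.nugget_sd, len(xs))
        table[name] = vals
    table["quality_flag"] = 1
    table["track"] = track
    return table


def generate_plots(truth: TruthBundle, config: SceneConfig) -> pd.DataFrame:
    """Circular plot inventory whose allometric AGC tracks the truth field.

    Plot centres are uniform in the extent; the culm count is scaled so the
    summed per-culm carbon of lognormal DBH draws matches the AGC truth at
    the centre, leaving only culm-sampling noise.
    """
    if config.n_plots < 2:
        raise ValueError("need at least two plots")
    rng = _rng(config, 4)
    xmin, ymin, xmax, ymax = config.extent
    margin = config.cell_size
    xs = rng.uniform(xmin + margin, xmax - margin, config.n_plots)
    ys = rng.uniform(ymin + margin, ymax - margin, config.n_plots)
    target = truth.agc_field.sample_bilinear(xs, ys)

    mu, sigma = config.dbh_lognormal
    area = allometry.plot_area(config.plot_radius)
    # expected carbon of one culm under the DBH distribution (Monte Carlo,
    # local generator so plot draws stay aligned across configs)
    probe = np.exp(np.random.default_rng([config.seed, 5])
                   .normal(mu, sigma, 512))
    kg_per_culm = float(np.mean([allometry.culm_carbon(d) for d in probe]))

    records = []
    lo, hi = config.culm_density
    for i in range(config.n_plots):
        target_kg = max(target[i], 0.0) * (area / 10000.0) * 1000.0
        n_culms = int(np.clip(round(target_kg / kg_per_culm), lo, hi))
        dbh = np.exp(rng.normal(mu, sigma, n_culms))
        records.append({"plot_id": i, "x": xs[i], "y": ys[i],
                        "radius_m": config.plot_radius, "dbh_list": dbh})
    return allometry.plots_from_dbh(records)


def generate_scene(config: SceneConfig):
    """Convenience wrapper: (truth, footprints, plots) for one config."""
    dem = generate_dem(config)
    truth = generate_truth_fields(dem, config)
    return truth, sample_footprints(truth, config), generate_plots(truth, config)
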