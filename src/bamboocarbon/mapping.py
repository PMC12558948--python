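"""Wall-to-wall AGC mapping and zonal summaries.

The selected regression model is applied per pixel across the interpolated
predictor surfaces to produce the carbon density raster (Mg/ha); the zonal
summary reports min/mean/max density and the total stock in Mg, where the
pixel area follows from the cell size (25 m cells are 0.0625 ha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import GridSurface

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZonalSummary:
    mean: float
    min: float
    max: float
    total_stock: float
    pixel_count: int
    pixel_area_ha: float


def predict_raster(model, surfaces: dict, feature_names=None,
                   mask: GridSurface | None = None,
                   clip_negative: bool = True) -> GridSurface:
    """Per-pixel model prediction over aligned predictor surfaces.

    ``feature_names`` fixes the column order fed to the model (defaults to
    the model's ``feature_names_in_`` or the surface-map order). Pixels that
    are nodata in any predictor, or masked out, become nodata. Negative
    predictions are clipped to zero (tree ensembles can extrapolate slightly
    below zero); the clipped-pixel count is logged.
    """
    if feature_names is None:
        feature_names = list(getattr(model, "feature_names_in_",
                                     surfaces.keys()))
    missing = [n for n in feature_names if n not in surfaces]
    if missing:
        raise KeyError(f"missing predictor surface(s): {missing}")
    ref = surfaces[feature_names[0]]
    valid = ref.mask()
    for name in feature_names[1:]:
        g = surfaces[name]
        if not g.same_georef(ref):
            raise ValueError("predictor surfaces must share georeferencing")
        valid &= g.mask()
    if mask is not None:
        if not mask.same_georef(ref):
            raise ValueError("mask must share georeferencing")
        valid &= mask.mask()

    out = np.full(ref.values.shape, ref.nodata, dtype=float)
    if valid.any():
        X = np.column_stack([surfaces[n].values[valid] for n in feature_names])
        pred = np.asarray(model.predict(X), dtype=float)
        if clip_negative:
            n_clip = int((pred < 0).sum())
            if n_clip:
                log.info("predict_raster: clipped %d negative pixels", n_clip)
            pred = np.clip(pred, 0.0, None)
        out[valid] = pred
    return ref.copy_with(out)


def zonal_summary(agc: GridSurface) -> ZonalSummary:
    """Statistics over valid pixels of an AGC raster.

    The total stock is computed both as sum(pixel value x pixel area) and as
    mean x valid area; the two routes are asserted equal before reporting.
    """
    valid = agc.mask()
    if not valid.any():
        raise ValueError("AGC raster is entirely nodata")
    v = agc.values[valid]
    area_ha = (agc.cell_size ** 2) / 10000.0
    total = float(np.sum(v * area_ha))
    alt = float(v.mean() * v.size * area_ha)
    if not np.isclose(total, alt, rtol=1e-6):
        raise AssertionError("stock accounting mismatch between summation "
                             "routes")  # pragma: no cover
    return ZonalSummary(mean=float(v.mean()), min=float(v.min()),
                        max=float(v.max()), total_stock=total,
                        pixel_count=int(v.size), pixel_area_ha=area_ha)
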