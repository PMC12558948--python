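"""Georeferenced single-band rasters on a projected grid.

The package works in projected metres (x east, y north). A :class:`GridSurface`
stores its origin at the upper-left *corner* of the upper-left cell; cell
centres sit at half-cell offsets. Rasters are exchanged as ESRI ASCII grid
(``.asc``) files, a plain-text format understood by every GIS, with nodata
sentinel -9999.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class GridSurface:
    """Single-band float raster with simple georeferencing.

    Parameters
    ----------
    x_origin, y_origin:
        Projected coordinates of the upper-left corner of the upper-left
        cell. Row index increases southwards.
    cell_size:
        Square cell edge length in metres.
    values:
        2-D float array, shape ``(n_rows, n_cols)``; ``nodata`` marks gaps.
    """

    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridSurface values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.cell_size,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin,
        )

    def same_georef(self, other: "GridSurface", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def mask(self) -> np.ndarray:
        """Boolean array, True where a cell holds a valid value."""
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, each (n_rows, n_cols)."""
        half = self.cell_size / 2.0
        xs = self.x_origin + half + self.cell_size * np.arange(self.n_cols)
        ys = self.y_origin - half - self.cell_size * np.arange(self.n_rows)
        return np.meshgrid(xs, ys)

    def copy_with(self, values: np.ndarray) -> "GridSurface":
        return GridSurface(self.x_origin, self.y_origin, self.cell_size,
                           np.asarray(values, dtype=float), self.nodata)

    # ------------------------------------------------------------------
    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation at arbitrary points.

        Values are interpolated between the four surrounding cell centres;
        points in the half-cell margin are clamped to the edge centres. If any
        contributing centre is nodata the result is NaN. Points outside the
        grid footprint return NaN.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        half = self.cell_size / 2.0
        # fractional index of the point in cell-centre space
        fc = (x - self.x_origin - half) / self.cell_size
        fr = (self.y_origin - half - y) / self.cell_size
        xmin, ymin, xmax, ymax = self.extent
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

        fc = np.clip(fc, 0.0, self.n_cols - 1.0)
        fr = np.clip(fr, 0.0, self.n_rows - 1.0)
        c0 = np.clip(np.floor(fc).astype(int), 0, max(self.n_cols - 2, 0))
        r0 = np.clip(np.floor(fr).astype(int), 0, max(self.n_rows - 2, 0))
        c1 = np.minimum(c0 + 1, self.n_cols - 1)
        r1 = np.minimum(r0 + 1, self.n_rows - 1)
        tx = fc - c0
        ty = fr - r0

        v = self.values
        q00, q01 = v[r0, c0], v[r0, c1]
        q10, q11 = v[r1, c0], v[r1, c1]
        bad = np.zeros(x.shape, dtype=bool)
        for q in (q00, q01, q10, q11):
            bad |= np.isclose(q, self.nodata) | ~np.isfinite(q)
        out = ((1 - ty) * ((1 - tx) * q00 + tx * q01)
               + ty * ((1 - tx) * q10 + tx * q11))
        out = np.where(bad | ~inside, np.nan, out)
        return out

    # ------------------------------------------------------------------
    def write_asc(self, path, metadata: dict | None = None) -> None:
        """Write as ESRI ASCII grid; optional metadata goes to a JSON sidecar."""
        path = Path(path)
        yll = self.y_origin - self.n_rows * self.cell_size
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x_origin!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        vals = np.where(self.mask(), self.values, self.nodata)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")
        if metadata is not None:
            Path(str(path) + ".meta.json").write_text(
                json.dumps(metadata, indent=1, sort_keys=True))


def read_asc(path) -> GridSurface:
    """Read an ESRI ASCII grid written by :meth:`GridSurface.write_asc`."""
    path = Path(path)
    hdr: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {values.shape} does not match header")
    cell = hdr["cellsize"]
    y_origin = hdr["yllcorner"] + nrows * cell
    return GridSurface(hdr["xllcorner"], y_origin, cell, values,
                       nodata=hdr.get("nodata_value", NODATA))


def resample_bilinear(grid: GridSurface, target_cell: float) -> GridSurface:
    """Resample a raster to a new cell size with bilinear interpolation.

    Nodata-aware: a target cell whose interpolation stencil touches a nodata
    source cell becomes nodata. Mirrors the DEM preprocessing convention of
    resampling fine elevation data onto the 25 m analysis grid.
    """
    if target_cell <= 0:
        raise ValueError("target_cell must be positive")
    xmin, ymin, xmax, ymax = grid.extent
    if target_cell > (xmax - xmin) or target_cell > (ymax - ymin):
        raise ValueError("target cell size is coarser than the grid extent")
    n_cols = int(round((xmax - xmin) / target_cell))
    n_rows = int(round((ymax - ymin) / target_cell))
    out = GridSurface(grid.x_origin, grid.y_origin, target_cell,
                      np.zeros((n_rows, n_cols)), nodata=grid.nodata)
    gx, gy = out.cell_centres()
    sampled = grid.sample_bilinear(gx.ravel(), gy.ravel()).reshape(n_rows, n_cols)
    out.values = np.where(np.isfinite(sampled), sampled, grid.nodata)
    return out
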