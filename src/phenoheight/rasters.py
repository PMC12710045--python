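"""Georeferenced single-band rasters (DSM, DTM, CHM) on a regular grid.

The grid convention follows the usual raster layout: row 0 is the northern
(top) edge, ``values[r, c]`` has its cell centre at
``(x0 + (c + 0.5) * cell, y0 - (r + 0.5) * cell)`` where ``(x0, y0)`` is the
top-left corner. Persistence uses the ESRI ASCII grid format, a plain-text
raster interchange format readable by GDAL/QGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A 2-D elevation/height surface with nodata handling."""

    values: np.ndarray
    origin: tuple[float, float]  # (x, y) of the top-left corner
    cell: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell, x0 + ncols * self.cell, y0)

    def x_centers(self) -> np.ndarray:
        x0, _ = self.origin
        return x0 + (np.arange(self.shape[1]) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        _, y0 = self.origin
        return y0 - (np.arange(self.shape[0]) + 0.5) * self.cell

    def mask(self) -> np.ndarray:
        """Boolean array, True where a cell holds valid data."""
        return self.values != self.nodata

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask()] = fill
        return out

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear sample at planar coordinates (clamped at the edges)."""
        from scipy.interpolate import RegularGridInterpolator

        yc = self.y_centers()
        interp = RegularGridInterpolator(
            (yc[::-1], self.x_centers()),
            self.filled()[::-1, :],
            bounds_error=False,
            fill_value=None,  # extrapolate, then clamp below
        )
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        half = self.cell / 2
        xq = np.clip(x, xmin + half, xmax - half)
        yq = np.clip(y, ymin + half, ymax - half)
        return interp(np.column_stack([yq.ravel(), xq.ravel()])).reshape(x.shape)

    def grids_match(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell - other.cell) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


def write_ascii_grid(raster: RasterGrid, path: str) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    nrows, ncols = raster.shape
    xll, yll = raster.origin[0], raster.origin[1] - nrows * raster.cell
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(xll)!r}\n"
        f"yllcorner {float(yll)!r}\n"
        f"cellsize {float(raster.cell)!r}\n"
        f"NODATA_value {float(raster.nodata)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.6f")


def read_ascii_grid(path: str) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(values, origin, cell, nodata=header["nodata_value"])


def grid_for_bounds(
    bounds: tuple[float, float, float, float], cell: float
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Origin and shape of the grid covering ``bounds`` at ``cell`` size."""
    xmin, ymin, xmax, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty extent")
    ncols = max(1, int(np.ceil((xmax - xmin) / cell - 1e-9)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cell - 1e-9)))
    return (xmin, ymin + nrows * cell), (nrows, ncols)
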