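"""Per-plot plant-height extraction from surface rasters.

Two extraction rules are provided, matching the two sensor branches of a
UAV campaign:

* **RGB branch** — no bare-ground flight exists, so plot height is the
  spread between a high percentile (top of the stems) and a low percentile
  (visible soil) of the within-plot DSM values. This makes the estimate
  independent of the absolute elevation datum.
* **LiDAR branch** — a CHM is available, so plot height is a robust
  aggregate (default 95th percentile) of within-plot canopy heights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping, shape

from .rasters import RasterGrid
from .synthetic_field import FieldDesign


@dataclass
class PlotMask:
    """One plot's demarcation polygon at one time point."""

    plot_id: str
    polygon: Polygon
    time_point: int = 0

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"mask polygon for {self.plot_id} is not simple")


@dataclass
class PlotHeightSeries:
    """Plots x time-points height matrices for one sensor.

    ``extracted`` is the raw UAV-derived height, ``predicted`` the calibrated
    height, ``measured`` the manual ground truth where available. Missing
    entries are NaN (undefined), never zero.
    """

    extracted: pd.DataFrame
    sensor: str
    predicted: pd.DataFrame | None = None
    measured: pd.DataFrame | None = None

    @property
    def plot_ids(self) -> list[str]:
        return list(self.extracted.index)

    @property
    def time_points(self) -> list[int]:
        return list(self.extracted.columns)

    def to_long(self) -> pd.DataFrame:
        frames = []
        for name, df in [
            ("extracted_m", self.extracted),
            ("predicted_m", self.predicted),
            ("measured_m", self.measured),
        ]:
            if df is None:
                continue
            long = df.stack(future_stack=True).rename(name).reset_index()
            long.columns = ["plot_id", "time", name]
            frames.append(long.set_index(["plot_id", "time"]))
        out = pd.concat(frames, axis=1).reset_index()
        out.insert(2, "sensor", self.sensor)
        return out

    def to_csv(self, path: str) -> None:
        self.to_long().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str) -> "PlotHeightSeries":
        long = pd.read_csv(path)
        sensor = str(long["sensor"].iloc[0])
        mats: dict[str, pd.DataFrame | None] = {}
        for name in ["extracted_m", "predicted_m", "measured_m"]:
            if name in long.columns and long[name].notna().any():
                mats[name] = long.pivot(index="plot_id", columns="time", values=name)
            else:
                mats[name] = None
        return cls(
            extracted=mats["extracted_m"],
            sensor=sensor,
            predicted=mats["predicted_m"],
            measured=mats["measured_m"],
        )


def build_plot_masks(
    design: FieldDesign, shrink: float = 0.1, time_point: int = 0
) -> list[PlotMask]:
    """Rectangular demarcation masks, inset by ``shrink`` of each dimension.

    ``shrink`` is applied per side, so a 0.1 shrink turns a 4.5 x 5.0 m plot
    into a 3.6 x 4.0 m mask. Canopy growth across flights is accommodated by
    passing a smaller shrink at later time points.
    """
    if not 0.0 <= shrink < 0.5:
        raise ValueError("shrink must lie in [0, 0.5)")
    masks = []
    for pid, i in zip(design.plot_ids(), range(design.n_plots)):
        xmin, ymin, xmax, ymax = design.plot_rectangle(i)
        dx = (xmax - xmin) * shrink
        dy = (ymax - ymin) * shrink
        poly = box(xmin + dx, ymin + dy, xmax - dx, ymax - dy)
        masks.append(PlotMask(pid, poly, time_point))
    return masks


def zonal_values(raster: RasterGrid, mask: PlotMask) -> np.ndarray:
    """All non-nodata cell values whose centres fall inside the polygon.

    Cell centres exactly on the polygon boundary are excluded (half-open
    convention), so adjacent masks never double-count a cell.
    """
    xmin, ymin, xmax, ymax = mask.polygon.bounds
    xs = raster.x_centers()
    ys = raster.y_centers()
    ci = np.where((xs > xmin - raster.cell) & (xs < xmax + raster.cell))[0]
    ri = np.where((ys > ymin - raster.cell) & (ys < ymax + raster.cell))[0]
    if ci.size == 0 or ri.size == 0:
        raise ValueError(f"mask {mask.plot_id} does not intersect the raster")
    X, Y = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(mask.polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    sub = raster.values[np.ix_(ri, ci)]
    vals = sub[inside & (sub != raster.nodata)]
    if vals.size == 0:
        raise ValueError(f"mask {mask.plot_id} covers no valid cells")
    return vals


def _percentile_band(values: np.ndarray, band: tuple[float, float], take: str) -> float:
    qs = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1.0)
    pct = np.percentile(values, qs)  # linear interpolation (type-7)
    return float(pct.max() if take == "max" else pct.min())


def extract_rgb_ph(
    dsm: RasterGrid,
    mask: PlotMask,
    p_low: tuple[float, float] = (1.0, 2.0),
    p_high: tuple[float, float] = (95.0, 98.0),
    min_cells: int = 20,
) -> float:
    """Percentile-spread plant height from a single-surface DSM.

    Height = max of the high-percentile band (stem tops) minus min of the
    low-percentile band (soil floor). Monotonicity of percentiles makes this
    equal the (p_high[1] - p_low[0]) spread; both band endpoints are
    evaluated explicitly. Invariant to a constant elevation offset.
    """
    values = zonal_values(dsm, mask)
    if values.size < min_cells:
        raise ValueError(f"mask {mask.plot_id}: too few cells ({values.size})")
    top = _percentile_band(values, p_high, "max")
    floor = _percentile_band(values, p_low, "min")
    return max(top - floor, 0.0)


def _mean_top_decile(v: np.ndarray) -> float:
    cut = np.percentile(v, 90)
    top = v[v >= cut]
    return float(top.mean()) if top.size else float(v.max())


_AGGREGATORS = {
    "p95": lambda v: float(np.percentile(v, 95)),
    "p99": lambda v: float(np.percentile(v, 99)),
    "max": lambda v: float(np.max(v)),
    "mean_top_decile": _mean_top_decile,
}


def extract_lidar_ph(
    chm: RasterGrid,
    mask: PlotMask,
    aggregator: str = "p95",
    min_cells: int = 20,
) -> float:
    """Robust aggregate of within-plot CHM values (default 95th percentile)."""
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    values = zonal_values(chm, mask)
    if values.size < min_cells:
        raise ValueError(f"mask {mask.plot_id}: too few cells ({values.size})")
    return _AGGREGATORS[aggregator](values)


def assemble_series(
    records: pd.DataFrame | list[tuple[str, int, float]],
    sensor: str,
) -> PlotHeightSeries:
    """Pivot (plot_id, time, value) records into a plots x times matrix.

    A failed extraction is recorded as NaN, never zero. Duplicate
    (plot, time) entries raise.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["plot_id", "time", "value"])
    if records.duplicated(["plot_id", "time"]).any():
        raise ValueError("duplicate (plot, time) entries")
    mat = records.pivot(index="plot_id", columns="time", values="value")
    return PlotHeightSeries(extracted=mat, sensor=sensor)


def write_masks_geojson(masks: list[PlotMask], path: str) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": m.plot_id, "time_point": m.time_point},
            "geometry": mapping(m.polygon),
        }
        for m in masks
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_masks_geojson(path: str) -> list[PlotMask]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        PlotMask(
            f["properties"]["plot_id"],
            shape(f["geometry"]),
            int(f["properties"].get("time_point", 0)),
        )
        for f in fc["features"]
    ]
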