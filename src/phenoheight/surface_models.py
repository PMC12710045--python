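"""Point-cloud processing chain: resample, denoise, classify ground, rasterize.

The chain mirrors a standard LiDAR canopy-height workflow: voxel thinning for
even density, statistical-outlier removal, morphological ground filtering,
per-cell-maximum DSM, TIN-interpolated DTM, and CHM = DSM - DTM.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

from .pointcloud import GROUND, NOISE, NON_GROUND, PointCloud
from .rasters import RasterGrid, grid_for_bounds


def voxel_resample(cloud: PointCloud, cell: float) -> PointCloud:
    """Keep, per occupied 3-D voxel, the point closest to the voxel centroid.

    The output is always a subset of the input points.
    """
    if cell <= 0:
        raise ValueError("voxel size must be positive")
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    ix = np.floor(cloud.x / cell).astype(np.int64)
    iy = np.floor(cloud.y / cell).astype(np.int64)
    iz = np.floor(cloud.z / cell).astype(np.int64)
    d2 = (
        (cloud.x - (ix + 0.5) * cell) ** 2
        + (cloud.y - (iy + 0.5) * cell) ** 2
        + (cloud.z - (iz + 0.5) * cell) ** 2
    )
    # sort by (voxel, distance) then take the first point of each voxel run
    key = np.lexsort((d2, iz, iy, ix))
    sx, sy, sz = ix[key], iy[key], iz[key]
    new_voxel = np.ones(len(cloud), dtype=bool)
    new_voxel[1:] = (sx[1:] != sx[:-1]) | (sy[1:] != sy[:-1]) | (sz[1:] != sz[:-1])
    keep = np.sort(key[new_voxel])
    return cloud.subset(keep)


def denoise(cloud: PointCloud, k_neighbors: int = 8, n_sigma: float = 3.0) -> PointCloud:
    """Statistical outlier removal.

    Points whose mean distance to their ``k_neighbors`` nearest neighbours
    exceeds the global mean by more than ``n_sigma`` standard deviations are
    dropped.
    """
    if k_neighbors >= len(cloud):
        raise ValueError("k_neighbors must be smaller than the cloud size")
    pts = np.column_stack([cloud.x, cloud.y, cloud.z])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k_neighbors + 1)
    mean_knn = dist[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + n_sigma * mean_knn.std()
    keep = mean_knn <= thresh
    return cloud.subset(keep)


def classify_ground(
    cloud: PointCloud,
    cell: float = 0.25,
    slope_tol: float = 0.10,
    opening_radius_m: float = 4.0,
) -> PointCloud:
    """Morphological ground filter: per-cell minima + opening + tolerance test.

    A minimum-z grid is built at ``cell`` resolution, gaps are filled from the
    nearest occupied cell, and a grey-scale morphological opening with a
    window of ``opening_radius_m`` strips off-terrain blobs (canopies) whose
    footprint is smaller than the window. Points within ``slope_tol`` metres
    above the opened surface are labelled ground, the rest non-ground.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    bounds = cloud.bounds()
    origin, shape = grid_for_bounds(bounds, cell)
    nrows, ncols = shape
    col = np.clip(((cloud.x - origin[0]) / cell).astype(int), 0, ncols - 1)
    row = np.clip(((origin[1] - cloud.y) / cell).astype(int), 0, nrows - 1)
    if nrows == 1 and ncols == 1:
        # degenerate extent: treat the global minimum as the ground datum
        zmin = cloud.z.min()
        labels = np.where(cloud.z <= zmin + slope_tol, GROUND, NON_GROUND)
        out = cloud.subset(np.arange(len(cloud)))
        out.classification = labels.astype(np.int8)
        return out

    min_grid = np.full(shape, np.inf)
    np.minimum.at(min_grid, (row, col), cloud.z)
    empty = ~np.isfinite(min_grid)
    if empty.all():
        raise ValueError("no returns fall on the grid")
    if empty.any():
        # fill gaps from the nearest occupied cell
        _, (ri, ci) = ndimage.distance_transform_edt(empty, return_indices=True)
        min_grid = min_grid[ri, ci]

    half = max(1, int(np.ceil(opening_radius_m / cell)))
    size = 2 * half + 1
    opened = ndimage.grey_opening(min_grid, size=(size, size), mode="nearest")
    surface = opened[row, col]
    labels = np.where(cloud.z <= surface + slope_tol, GROUND, NON_GROUND)
    out = cloud.subset(np.arange(len(cloud)))
    out.classification = labels.astype(np.int8)
    return out


def rasterize_dsm(
    cloud: PointCloud,
    cell: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> RasterGrid:
    """Per-cell maximum z of all non-noise points; empty cells are nodata."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    keep = cloud.classification != NOISE
    pts = cloud.subset(keep)
    if bounds is None:
        bounds = pts.bounds()
    origin, shape = grid_for_bounds(bounds, cell)
    nrows, ncols = shape
    col = np.clip(((pts.x - origin[0]) / cell).astype(int), 0, ncols - 1)
    row = np.clip(((origin[1] - pts.y) / cell).astype(int), 0, nrows - 1)
    values = np.full(shape, -np.inf)
    np.maximum.at(values, (row, col), pts.z)
    grid = RasterGrid(np.zeros(shape), origin, cell)
    out = np.where(np.isfinite(values), values, grid.nodata)
    grid.values = out
    return grid


def interpolate_dtm(
    cloud: PointCloud,
    cell: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> RasterGrid:
    """TIN (Delaunay/linear) interpolation of ground points onto the grid.

    Cells outside the convex hull of the ground returns are filled by
    nearest-neighbour extrapolation.
    """
    ground = cloud.subset(cloud.classification == GROUND)
    if len(ground) < 3:
        raise ValueError("need at least 3 ground points for a terrain model")
    if bounds is None:
        bounds = ground.bounds()
    origin, shape = grid_for_bounds(bounds, cell)
    grid = RasterGrid(np.zeros(shape), origin, cell)
    X, Y = np.meshgrid(grid.x_centers(), grid.y_centers())
    pts = np.column_stack([ground.x, ground.y])
    try:
        lin = LinearNDInterpolator(pts, ground.z)
    except Exception as exc:  # QhullError on collinear input
        raise ValueError("ground points are degenerate (collinear)") from exc
    values = lin(X, Y)
    hole = np.isnan(values)
    if hole.any():
        near = NearestNDInterpolator(pts, ground.z)
        values[hole] = near(X[hole], Y[hole])
    grid.values = values
    return grid


def compute_chm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Canopy height model: elementwise DSM - DTM, clamped at zero.

    Nodata in either operand propagates to the output.
    """
    if not dsm.grids_match(dtm):
        raise ValueError("DSM and DTM grids do not match (origin/cell/shape)")
    chm = RasterGrid(np.zeros(dsm.shape), dsm.origin, dsm.cell, nodata=dsm.nodata)
    valid = dsm.mask() & dtm.mask()
    values = np.full(dsm.shape, chm.nodata)
    diff = dsm.values - dtm.values
    values[valid] = np.maximum(diff[valid], 0.0)
    chm.values = values
    return chm


def ground_classification_scores(cloud: PointCloud) -> dict[str, float]:
    """Precision/recall of the ground label against simulator truth."""
    if cloud.truth_class is None:
        raise ValueError("cloud carries no truth labels")
    pred = cloud.classification == GROUND
    true = cloud.truth_class == GROUND
    tp = float(np.sum(pred & true))
    precision = tp / max(pred.sum(), 1)
    recall = tp / max(true.sum(), 1)
    return {"precision": precision, "recall": recall}
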