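"""Terrain covariates derived from a DEM.

Provides Horn slope/aspect, D8 flow accumulation (optionally weighted by a
water-source raster), the compound topographic wetness index
``CTI = ln(A_s / tan(beta))``, and Euclidean distance to the coast, where the
coastline is the set of zero-elevation cells.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .gridio import DEMGrid

__all__ = [
    "TerrainStack",
    "slope_aspect",
    "flow_accumulation",
    "cti",
    "distance_to_coast",
    "terrain_stack",
    "sample_at_points",
]

#: Default floor for tan(slope) in the CTI, tan of 0.1 degrees.
DEFAULT_TAN_FLOOR = math.tan(math.radians(0.1))

# D8 neighbor offsets in row-major scan order; ties between equally steep
# neighbors resolve to the first entry.
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class TerrainStack:
    """Bundle of terrain rasters sharing the source DEM's grid."""

    slope: DEMGrid          # radians
    aspect_dev: DEMGrid     # absolute degrees from north, 0-180
    accumulation: DEMGrid   # upslope contributing area per unit contour width, m^2/m
    cti: DEMGrid            # unitless
    dist_coast: DEMGrid     # metres

    def as_dict(self) -> dict[str, DEMGrid]:
        return {
            "slope": self.slope,
            "aspect_dev": self.aspect_dev,
            "accumulation": self.accumulation,
            "cti": self.cti,
            "dist_coast": self.dist_coast,
        }


def slope_aspect(dem: DEMGrid) -> tuple[DEMGrid, DEMGrid]:
    """Slope (radians) and aspect deviation from north (degrees, 0-180).

    Gradients use Horn's third-order finite difference on the 3x3
    neighborhood (edge cells replicate the border). Aspect is reported as the
    absolute angular deviation of the downslope azimuth from north, so a
    north-facing cell scores 0 and a south-facing cell 180; flat cells score
    0 by convention.
    """
    z = np.pad(dem.values, 1, mode="edge")
    c = dem.cellsize
    # Horn weights; row 0 of the array is the northern edge.
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * c)
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * c)
    slope = np.arctan(np.hypot(gx, gy))
    # Downslope direction is -(gx, gy); azimuth measured from north.
    azimuth = np.degrees(np.arctan2(-gx, -gy))
    aspect_dev = np.abs(azimuth)
    aspect_dev[slope == 0] = 0.0
    return dem.like(slope), dem.like(aspect_dev)


def _flow_directions(dem: DEMGrid) -> np.ndarray:
    """D8 receiver index per cell (flattened), -1 for sinks.

    Each cell drains to its steepest strictly-lower neighbor (drop divided by
    center distance); ties break to the first neighbor in row-major order.
    Flat cells drain toward the nearest flat-region cell that touches lower
    ground, assigned breadth-first.
    """
    z = dem.values
    nrows, ncols = z.shape
    recv = np.full(nrows * ncols, -1, dtype=np.int64)
    diag = math.sqrt(2.0)

    flats: list[tuple[int, int]] = []
    for r in range(nrows):
        for col in range(ncols):
            zc = z[r, col]
            if not np.isfinite(zc):
                continue
            best_slope = 0.0
            best = -1
            has_equal = False
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, col + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols):
                    continue
                zn = z[rr, cc]
                if not np.isfinite(zn):
                    continue
                drop = zc - zn
                if drop == 0:
                    has_equal = True
                    continue
                dist = diag if dr and dc else 1.0
                s = drop / dist
                if s > best_slope:
                    best_slope = s
                    best = rr * ncols + cc
            if best >= 0:
                recv[r * ncols + col] = best
            elif has_equal:
                flats.append((r, col))

    # Breadth-first flat resolution: flat cells adjacent to a resolved cell of
    # equal elevation drain into it, so flats empty toward their lower rim.
    queue = deque()
    pending = set()
    for r, col in flats:
        idx = r * ncols + col
        assigned = False
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, col + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and z[rr, cc] == z[r, col]:
                nidx = rr * ncols + cc
                if recv[nidx] >= 0:
                    recv[idx] = nidx
                    assigned = True
                    break
        if assigned:
            queue.append(idx)
        else:
            pending.add(idx)
    while queue:
        idx = queue.popleft()
        r, col = divmod(idx, ncols)
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, col + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and z[rr, cc] == z[r, col]:
                nidx = rr * ncols + cc
                if nidx in pending:
                    recv[nidx] = idx
                    pending.discard(nidx)
                    queue.append(nidx)
    # Cells left in `pending` are flat-bottomed closed depressions: sinks.
    return recv


def flow_accumulation(dem: DEMGrid, source_weights: np.ndarray | None = None) -> DEMGrid:
    """D8 specific catchment area, m^2 per metre of contour width.

    Each cell contributes ``weight * cellsize**2`` of source area and passes
    its full accumulation to a single downslope receiver; the result is
    divided by the cellsize to express area per unit contour width.
    """
    z = dem.values
    if source_weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(source_weights, dtype=float)
        if w.shape != z.shape:
            raise ValueError("source_weights shape does not match the DEM")
        if np.nanmin(w) < 0:
            raise ValueError("source_weights must be non-negative")
    recv = _flow_directions(dem)
    n = z.size
    acc = (w * dem.cellsize**2).ravel().astype(float)
    acc[~np.isfinite(acc)] = 0.0

    indeg = np.zeros(n, dtype=np.int64)
    valid = recv >= 0
    np.add.at(indeg, recv[valid], 1)
    queue = deque(np.flatnonzero(indeg == 0).tolist())
    seen = 0
    while queue:
        idx = queue.popleft()
        seen += 1
        tgt = recv[idx]
        if tgt >= 0:
            acc[tgt] += acc[idx]
            indeg[tgt] -= 1
            if indeg[tgt] == 0:
                queue.append(tgt)
    if seen != n:  # pragma: no cover - D8 receivers strictly descend, no cycles
        raise RuntimeError("cycle detected in flow routing")
    out = acc.reshape(z.shape) / dem.cellsize
    out[~np.isfinite(z)] = np.nan
    return dem.like(out)


def cti(
    dem: DEMGrid,
    source_weights: np.ndarray | None = None,
    tan_floor: float = DEFAULT_TAN_FLOOR,
) -> DEMGrid:
    """Compound topographic index ``ln(A_s / tan(beta))``.

    ``tan(beta)`` is floored at `tan_floor` so flat cells stay finite; the
    contributing area is floored at one weighted cell of source so the
    logarithm is defined even under zero source weights.
    """
    acc = flow_accumulation(dem, source_weights).values
    slope = slope_aspect(dem)[0].values
    tanb = np.maximum(np.tan(slope), tan_floor)
    a_s = np.maximum(acc, 1e-12)
    return dem.like(np.log(a_s / tanb))


def distance_to_coast(dem: DEMGrid, points: np.ndarray) -> np.ndarray:
    """Euclidean distance (m) from each point to the nearest coast cell center.

    The coastline is the set of zero-elevation cells of the DEM.
    """
    coast = np.argwhere(dem.values == 0.0)
    if coast.size == 0:
        raise ValueError("DEM has no zero-elevation cells; coastline undefined")
    cx = dem.xllcorner + (coast[:, 1] + 0.5) * dem.cellsize
    cy = dem.yllcorner + (dem.nrows - coast[:, 0] - 0.5) * dem.cellsize
    tree = cKDTree(np.column_stack([cx, cy]))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, _ = tree.query(pts)
    return dist


def terrain_stack(dem: DEMGrid, source_weights: np.ndarray | None = None) -> TerrainStack:
    """All terrain covariates for every cell of the DEM."""
    slope, aspect = slope_aspect(dem)
    acc = flow_accumulation(dem, source_weights)
    wet = cti(dem, source_weights)
    x, y = dem.cell_centers()
    dist = distance_to_coast(dem, np.column_stack([x.ravel(), y.ravel()]))
    return TerrainStack(slope, aspect, acc, wet, dem.like(dist.reshape(dem.shape)))


def sample_at_points(grid: DEMGrid, points: np.ndarray) -> np.ndarray:
    """Nearest-cell values of `grid` at (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    col = np.clip(((pts[:, 0] - grid.xllcorner) / grid.cellsize).astype(int), 0, grid.ncols - 1)
    row = np.clip(
        np.floor(grid.nrows - (pts[:, 1] - grid.yllcorner) / grid.cellsize).astype(int),
        0,
        grid.nrows - 1,
    )
    return grid.values[row, col]
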