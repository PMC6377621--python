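"""Raster grid container and ESRI ASCII grid I/O.

All rasters in this package share one registration convention: values are
cell centers, row 0 is the northern edge, x increases eastward and y
northward, and coordinates are in metres.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["DEMGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class DEMGrid:
    """Elevation (or any scalar) raster with square cells.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; NaN marks nodata internally.
    cellsize : float
        Cell edge length in metres.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the lower-left cell.
    nodata : float
        Marker written to/parsed from ESRI ASCII files.
    """

    values: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")
        if not np.isfinite(self.values).any():
            raise ValueError("grid holds no finite cells")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell center; row 0 is the northern edge."""
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-style (x, y) arrays for every cell center."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xllcorner + (cols + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def contains(self, x: float, y: float) -> bool:
        return (
            self.xllcorner <= x <= self.xllcorner + self.ncols * self.cellsize
            and self.yllcorner <= y <= self.yllcorner + self.nrows * self.cellsize
        )

    def like(self, values: np.ndarray) -> "DEMGrid":
        """New grid with identical georeferencing but different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("shape mismatch with template grid")
        return DEMGrid(values, self.cellsize, self.xllcorner, self.yllcorner, self.nodata)


def read_ascii_grid(path: str | Path) -> DEMGrid:
    """Read an ESRI ASCII raster (``.asc``)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = fh.read()
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header missing {key!r} in {path}")
    values = np.loadtxt(io.StringIO(body)).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return DEMGrid(
        values,
        cellsize=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=nodata,
    )


def write_ascii_grid(grid: DEMGrid, path: str | Path, fmt: str = "%.8g") -> None:
    """Write an ESRI ASCII raster; NaN cells become the nodata marker."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.8g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.8g}\n")
        fh.write(f"cellsize {grid.cellsize:.8g}\n")
        fh.write(f"NODATA_value {grid.nodata:.8g}\n")
        np.savetxt(fh, values, fmt=fmt)
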