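"""Elevation rasters in ESRI ASCII grid format.

A grid is stored in the standard raster convention: row 0 is the northern
edge, columns run west to east, and coordinates are projected meters.  The
ESRI ASCII header records the lower-left corner (``xllcorner``/``yllcorner``),
so the y coordinate of a cell center in row ``r`` is

    yllcorner + (nrows - r - 0.5) * cellsize
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationGrid", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class ElevationGrid:
    """A rectangular elevation raster on a projected (meter) grid.

    Parameters
    ----------
    values
        2-D array of elevations in meters; ``nodata`` marks missing cells.
    cell_size
        Grid spacing in meters (> 0).
    origin
        ``(x, y)`` of the lower-left corner of the grid in projected meters.
    nodata
        Sentinel for missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elevation grid must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata and are finite."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected ``(x, y)`` coordinates of every cell center.

        Returns two 2-D arrays aligned with :attr:`values`.
        """
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def contains(self, x: float, y: float) -> bool:
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0 <= x <= x0 + ncols * self.cell_size) and (
            y0 <= y <= y0 + nrows * self.cell_size
        )


@dataclass
class TerrainLayer:
    """A derived terrain variable aligned cell-for-cell with its source grid.

    ``variable`` is one of ``slope`` (degrees), ``aspect`` (degrees clockwise
    from north; NaN where undefined), ``ruggedness`` (TRI) or ``solar_gain``
    (Wh/m^2).  Cells that could not be computed (borders, nodata neighbours)
    are NaN.
    """

    variable: str
    values: np.ndarray
    grid: ElevationGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.values.shape:
            raise ValueError("layer not aligned with its grid")


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: no data rows found")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing required header field {key!r}")
        values = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    return ElevationGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def write_ascii_grid(grid: ElevationGrid, path: str | Path) -> None:
    """Write an :class:`ElevationGrid` as an ESRI ASCII grid."""
    nrows, ncols = grid.values.shape
    with Path(path).open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        out = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
        np.savetxt(fh, out, fmt="%.6f")
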