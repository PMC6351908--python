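"""Raster grid geometry and ESRI ASCII grid I/O.

All layers in a run share one planar grid: ``nrows x ncols`` square cells of
``cellsize`` metres, row 0 at the north edge.  Rasters travel as ESRI ASCII
grids (.asc), a plain-text format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class Grid:
    """Geometry shared by all rasters of a run.

    Parameters
    ----------
    nrows, ncols : int
        Grid shape; row 0 is the northern edge.
    cellsize : float
        Cell edge length in metres (cells are square).
    xllcorner, yllcorner : float
        Projected coordinates of the lower-left corner, metres.
    """

    nrows: int
    ncols: int
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_m2(self) -> float:
        return self.cellsize * self.cellsize

    @property
    def cell_area_hm2(self) -> float:
        """Cell area in hectares (1 hm2 = 10 000 m2)."""
        return self.cell_area_m2 / 1.0e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x_east, y_north) center coordinates, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xllcorner + (cols + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def congruent(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
        )


def require_congruent(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent(g):
            raise ValueError(f"grid geometry mismatch: {first} vs {g}")


def write_ascii_grid(
    path: str | Path,
    grid: Grid,
    data: np.ndarray,
    nodata: float = -9999.0,
    fmt: str = "%.10g",
) -> None:
    """Write one band as an ESRI ASCII grid."""
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xllcorner:.6f}\n"
        f"yllcorner {grid.yllcorner:.6f}\n"
        f"cellsize {grid.cellsize:.6f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    out = np.where(np.isfinite(data.astype(float)), data, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[Grid, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "nodata_value", "xllcenter", "yllcenter",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"missing ESRI ASCII header field {key!r} in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    # corner vs center registration
    if "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
    else:
        xll = header.get("xllcorner", 0.0)
    if "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        yll = header.get("yllcorner", 0.0)
    data = np.loadtxt(lines[n_header:]).reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    grid = Grid(nrows=nrows, ncols=ncols, cellsize=cellsize, xllcorner=xll, yllcorner=yll)
    return grid, data
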