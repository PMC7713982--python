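"""Single-band planar raster container and plain-text (ESRI ASCII grid) I/O.

Every covariate surface, simulated field, and output map in this package is a
:class:`GridLayer`: a north-up 2-D array of cell values on a square grid in a
planar (metric) coordinate system.  Row 0 is the northernmost row; the value of
a cell refers to its center.  Layers are serialized as ESRI ASCII grids
(``.asc``), a plain-text raster format readable by every GIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class GridLayer:
    """A single-band raster: values, cell size, lower-left origin, nodata.

    Parameters
    ----------
    values
        2-D array, row 0 = top (north).  Float layers use NaN internally for
        nodata; integer (categorical) layers use the ``nodata`` sentinel.
    cell
        Cell edge length in meters.
    origin
        ``(xll, yll)`` coordinates of the lower-left corner of the grid.
    nodata
        Sentinel written to/read from disk for missing cells.
    """

    values: np.ndarray
    cell: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    # ------------------------------------------------------------------ shape
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell, y0 + self.nrows * self.cell)

    @property
    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.ncols) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates per row, descending (row 0 = north)."""
        y0 = self.origin[1]
        return y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell

    def center_meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers)

    # --------------------------------------------------------------- indexing
    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; errors if outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell).astype(int)
        row = self.nrows - 1 - np.floor((y - y0) / self.cell).astype(int)
        # points exactly on the top/right boundary belong to the last cell
        col = np.where((x == x0 + self.ncols * self.cell), self.ncols - 1, col)
        row = np.where((y == y0 + self.nrows * self.cell), 0, row)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            raise ValueError("point(s) outside grid extent")
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point (cell-as-pixel semantics)."""
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def valid_mask(self) -> np.ndarray:
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            return ~np.isnan(v) & (v != self.nodata)
        return v != self.nodata

    def aligned_with(self, other: "GridLayer") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cell, other.cell)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def like(self, values: np.ndarray) -> "GridLayer":
        """New layer with the same geometry and the given values."""
        return GridLayer(values, self.cell, self.origin, self.nodata)

    def copy(self) -> "GridLayer":
        return GridLayer(self.values.copy(), self.cell, self.origin, self.nodata)

    # --------------------------------------------------------------------- IO
    def write_ascii(self, path) -> None:
        v = self.values.astype(float).copy()
        v[~self.valid_mask()] = self.nodata
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell:.6f}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, v, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path) -> "GridLayer":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        nodata = meta.get("nodata_value", NODATA_DEFAULT)
        values[values == nodata] = np.nan
        layer = cls(
            values,
            cell=meta["cellsize"],
            origin=(meta["xllcorner"], meta["yllcorner"]),
            nodata=nodata,
        )
        if layer.values.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError(f"shape mismatch reading {path}")
        return layer


def assert_aligned(layers: dict[str, GridLayer]) -> None:
    """Raise if any two layers in the mapping differ in geometry."""
    items = list(layers.items())
    if not items:
        return
    ref_name, ref = items[0]
    for name, layer in items[1:]:
        if not layer.aligned_with(ref):
            raise ValueError(f"layer {name!r} not aligned with {ref_name!r}")
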