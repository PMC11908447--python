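"""Lightweight planar raster grids.

All geometry in this package lives in a single projected, meter-based
Cartesian coordinate system.  A :class:`Grid` is a numpy array of cell
values plus an affine georeference (lower-left corner, square cell size)
and an optional nodata mask.  Cell membership semantics throughout the
package are *cell-center* based: a point belongs to the cell whose center
square contains it, and a cell belongs to a zone iff the value at its
center satisfies the zone rule.

Grids serialize to the ESRI ASCII-grid text format, which keeps every
artifact of a run plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import box


@dataclass
class Grid:
    """A raster of values on a regular square-cell grid.

    Parameters
    ----------
    data : ndarray of shape (ny, nx)
        Cell values.  Row ``i`` spans ``y0 + i*cell .. y0 + (i+1)*cell``
        (row 0 is the *southernmost* row).
    x0, y0 : float
        Coordinates of the lower-left (south-west) corner, meters.
    cell : float
        Cell edge length, meters.
    nodata : ndarray of bool, optional
        True where the cell carries no data.
    """

    data: np.ndarray
    x0: float
    y0: float
    cell: float
    nodata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"grid data must be 2-D, got shape {self.data.shape}")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nodata is not None:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.data.shape:
                raise ValueError(
                    f"nodata mask shape {self.nodata.shape} != data shape {self.data.shape}"
                )

    # -- georeferencing ------------------------------------------------

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (self.x0, self.y0, self.x0 + self.nx * self.cell, self.y0 + self.ny * self.cell)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-center coordinates, each shape (ny, nx)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
        )

    # -- point sampling ------------------------------------------------

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing points (x, y).

        Returns ``(i, j, inside)`` where ``inside`` flags points within the
        grid extent; indices of outside points are clipped.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.x0) / self.cell).astype(int)
        i = np.floor((y - self.y0) / self.cell).astype(int)
        inside = (i >= 0) & (i < self.ny) & (j >= 0) & (j < self.nx)
        return np.clip(i, 0, self.ny - 1), np.clip(j, 0, self.nx - 1), inside

    def values_at(self, x, y, fill: float = np.nan) -> np.ndarray:
        """Cell value at each point; ``fill`` outside the extent or at nodata."""
        i, j, inside = self.cell_index(x, y)
        out = self.data[i, j].astype(float)
        if self.nodata is not None:
            inside = inside & ~self.nodata[i, j]
        out = np.where(inside, out, fill)
        return out

    def mask_at(self, mask: np.ndarray, x, y) -> np.ndarray:
        """Evaluate a boolean cell mask at points; False outside the extent."""
        i, j, inside = self.cell_index(x, y)
        return np.asarray(mask, dtype=bool)[i, j] & inside

    def valid(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        if self.nodata is None:
            return np.ones(self.data.shape, dtype=bool)
        return ~self.nodata

    # -- constructors --------------------------------------------------

    @classmethod
    def full(cls, ny: int, nx: int, value: float, x0: float, y0: float, cell: float) -> "Grid":
        return cls(np.full((ny, nx), float(value)), x0, y0, cell)

    def like(self, data: np.ndarray, nodata: np.ndarray | None = None) -> "Grid":
        """New grid with this grid's georeference and the given data."""
        return Grid(data, self.x0, self.y0, self.cell, nodata)

    # -- text serialization (ESRI ASCII grid) --------------------------

    NODATA_VALUE = -9999.0

    def to_ascii(self, path: str | Path) -> None:
        data = self.data.copy()
        if self.nodata is not None:
            data[self.nodata] = self.NODATA_VALUE
        with open(path, "w") as fh:
            fh.write(f"ncols {self.nx}\n")
            fh.write(f"nrows {self.ny}\n")
            fh.write(f"xllcorner {self.x0!r}\n")
            fh.write(f"yllcorner {self.y0!r}\n")
            fh.write(f"cellsize {self.cell!r}\n")
            fh.write(f"NODATA_value {self.NODATA_VALUE!r}\n")
            # ESRI convention: first data row is the northernmost
            np.savetxt(fh, data[::-1], fmt="%.6g")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "Grid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)[::-1].copy()
        nodata_val = header.get("nodata_value", cls.NODATA_VALUE)
        mask = data == nodata_val
        return cls(
            data,
            header["xllcorner"],
            header["yllcorner"],
            header["cellsize"],
            nodata=mask if mask.any() else None,
        )


def polygonize_mask(mask: np.ndarray, grid: Grid) -> shapely.Geometry:
    """Dissolve the True cells of a boolean mask into a (Multi)Polygon.

    Consecutive True cells within each row are merged into rectangles
    first, then unioned; the result covers exactly the masked cells.
    Returns an empty polygon when no cell is set.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.data.shape:
        raise ValueError("mask shape does not match grid")
    boxes = []
    c = grid.cell
    for i in range(grid.ny):
        row = mask[i]
        if not row.any():
            continue
        # run-length encode the row
        padded = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        y_lo = grid.y0 + i * c
        y_hi = y_lo + c
        for j0, j1 in zip(starts, ends):
            boxes.append(box(grid.x0 + j0 * c, y_lo, grid.x0 + j1 * c, y_hi))
    if not boxes:
        return shapely.Polygon()
    return shapely.union_all(boxes)


def mask_area(mask: np.ndarray, grid: Grid) -> float:
    """Total area (m²) of the True cells."""
    return float(np.count_nonzero(mask)) * grid.cell**2
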