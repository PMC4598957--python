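"""Regular analysis lattice.

The analysis grid is a metric lattice of square cells (default 25 m), indexed
row-major from the south-west origin.  Cells are half-open intervals
``[x0 + j*c, x0 + (j+1)*c)`` in x and ``[y0 + i*c, y0 + (i+1)*c)`` in y, so
every point maps to exactly one cell and assignment is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Grid:
    """A regular square-cell lattice in projected metric coordinates.

    Parameters
    ----------
    x0, y0
        Coordinates (m) of the south-west corner of cell (0, 0).
    cell_size
        Side length of a cell in metres (default 25).
    nrows, ncols
        Lattice extent.  Row index increases northwards.
    active
        Boolean mask of cells that belong to the study area; defaults to all.
    """

    x0: float
    y0: float
    nrows: int
    ncols: int
    cell_size: float = 25.0
    active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")
        if self.active is None:
            self.active = np.ones((self.nrows, self.ncols), dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
            if self.active.shape != (self.nrows, self.ncols):
                raise ValueError("active mask shape does not match grid extent")

    # -- geometry ---------------------------------------------------------
    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares (0.0625 ha for the default 25 m cell)."""
        return self.cell_size**2 / 1e4

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_of(self, x, y):
        """Map points to (row, col); half-open cells, edge points go to the
        higher-index cell.  Points outside the lattice get index -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (row + 0.5) * self.cell_size
        return x, y

    def flat_index(self, row, col):
        """Row-major flat index over the full lattice."""
        return np.asarray(row) * self.ncols + np.asarray(col)

    def active_indices(self) -> np.ndarray:
        """Flat indices (row-major) of active cells, in row-major order."""
        return np.flatnonzero(self.active.ravel())

    def centers(self):
        """(x, y) arrays of the centres of all active cells, row-major order."""
        rows, cols = np.nonzero(self.active)
        return self.cell_center(rows, cols)
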