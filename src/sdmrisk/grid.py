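"""Planar raster grids and aligned predictor stacks.

All geometry is planar, in kilometres, on a regular south-up grid:
row 0 is the southernmost row, ``x = origin[0] + (col + 0.5) * cell_km``
and ``y = origin[1] + (row + 0.5) * cell_km`` give cell centres.
Nodata is carried as NaN in float grids plus an explicit validity mask so
integer-coded maps (binary, change codes) share the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd


@dataclass
class RasterGrid:
    """A single-band regular grid in a projected km frame.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values. NaN marks nodata in float grids.
    cell_km : float
        Cell edge length in km.
    origin : tuple of float
        (x, y) of the grid's lower-left corner, km.
    mask : ndarray of bool, optional
        True where the cell is valid. Defaults to non-NaN cells.
    """

    values: np.ndarray
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if self.mask is None:
            if np.issubdtype(self.values.dtype, np.floating):
                self.mask = ~np.isnan(self.values)
            else:
                self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape differs from values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_km, other.cell_km)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(x, y) centres for the given row/col indices, shape (n, 2)."""
        x = self.origin[0] + (np.asarray(cols) + 0.5) * self.cell_km
        y = self.origin[1] + (np.asarray(rows) + 0.5) * self.cell_km
        return np.column_stack([x, y])

    def valid_cell_centers(self) -> np.ndarray:
        rows, cols = np.nonzero(self.mask)
        return self.cell_centers(rows, cols)

    def index_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cols = np.floor((pts[:, 0] - self.origin[0]) / self.cell_km).astype(int)
        rows = np.floor((pts[:, 1] - self.origin[1]) / self.cell_km).astype(int)
        return rows, cols

    def contains(self, points: np.ndarray) -> np.ndarray:
        rows, cols = self.index_of(points)
        nr, nc = self.shape
        return (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Values at the cells containing the given points (NaN outside)."""
        rows, cols = self.index_of(points)
        inside = self.contains(points)
        out = np.full(len(rows), np.nan)
        r, c = rows[inside], cols[inside]
        vals = self.values[r, c].astype(float)
        vals[~self.mask[r, c]] = np.nan
        out[inside] = vals
        return out

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(values, self.cell_km, self.origin,
                          self.mask.copy() if mask is None else mask)


@dataclass
class EnvStack:
    """Named, aligned collection of predictor layers on one grid.

    ``layers`` maps name -> 2-D array; geometry and the shared nodata mask
    live once on the stack. ``registry`` carries per-layer metadata
    (code, units, source) where known.
    """

    layers: dict[str, np.ndarray]
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    registry: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must hold at least one layer")
        shapes = {np.asarray(v).shape for v in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError("all layers must share one shape")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}
        shape = next(iter(shapes))
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
            for v in self.layers.values():
                self.mask &= ~np.isnan(v)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError("mask shape differs from layer shape")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return RasterGrid(self.layers[name], self.cell_km, self.origin, self.mask)

    def template(self) -> RasterGrid:
        """An empty grid carrying this stack's geometry and mask."""
        vals = np.full(self.shape, np.nan)
        return RasterGrid(vals, self.cell_km, self.origin, self.mask)

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack({n: self.layers[n] for n in names}, self.cell_km,
                        self.origin, self.mask,
                        {n: self.registry[n] for n in names if n in self.registry})

    def to_frame(self) -> pd.DataFrame:
        """Valid cells as rows, layers as columns, with row/col index."""
        rows, cols = np.nonzero(self.mask)
        data = {name: arr[rows, cols] for name, arr in self.layers.items()}
        df = pd.DataFrame(data)
        df.index = pd.MultiIndex.from_arrays([rows, cols], names=["row", "col"])
        return df

    def extract(self, points: np.ndarray) -> pd.DataFrame:
        """Layer values at the cells containing the given (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pd.DataFrame({name: self[name].sample(pts) for name in self.layers})

    def map_from_values(self, values: np.ndarray) -> RasterGrid:
        """Scatter a vector over valid cells back into a grid."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.mask.sum():
            raise ValueError("value vector length differs from valid-cell count")
        out = np.full(self.shape, np.nan)
        out[self.mask] = values
        return RasterGrid(out, self.cell_km, self.origin, self.mask)


def require_aligned(*grids: RasterGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError("grids are not aligned (shape/cell/origin differ)")
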