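"""Core raster containers: single-band grids and aligned multi-band stacks.

All geometry lives in a local projected frame (metres). Grids are
north-up, row-major: row 0 is the northern edge, y decreases with row.
Cells are half-open, ``[x, x + cell_size)`` by ``(y - cell_size, y]``,
so a point on a cell's west/north edge belongs to that cell and every
in-bounds point maps to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridTransform", "RasterGrid", "RasterStack"]


@dataclass(frozen=True)
class GridTransform:
    """Geotransform of a north-up grid: top-left corner and square cell size."""

    origin_x: float
    origin_y: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    def cell_of(self, x, y):
        """Map point coordinates to (row, col) under the half-open convention."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)

    def center_of(self, row, col):
        """Coordinates of cell centres for (row, col) index arrays."""
        x = self.origin_x + (np.asarray(col, dtype=float) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row, dtype=float) + 0.5) * self.cell_size
        return x, y


@dataclass
class RasterGrid:
    """A single-band grid with a geotransform.

    Float grids encode nodata as NaN internally; integer grids (zone
    labels) use ``nodata_int`` (default -1).
    """

    data: np.ndarray
    transform: GridTransform
    name: str = "layer"
    nodata_int: int = -1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask (True where missing)."""
        if np.issubdtype(self.data.dtype, np.floating):
            return np.isnan(self.data)
        return self.data == self.nodata_int

    def aligned_with(self, other: "RasterGrid | RasterStack") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def values_at(self, x, y, ids=None):
        """Cell-value lookup at the containing cell (no interpolation).

        Raises ValueError naming out-of-bounds point ids.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.transform.cell_of(x, y)
        nrow, ncol = self.shape
        bad = (row < 0) | (row >= nrow) | (col < 0) | (col >= ncol)
        if bad.any():
            labels = np.asarray(ids)[bad] if ids is not None else np.flatnonzero(bad)
            raise ValueError(f"points outside raster bounds: {list(labels[:20])}")
        return self.data[row, col]

    def cell_centers(self):
        """(x, y) arrays of every cell centre, shape matching the grid."""
        rows, cols = np.indices(self.shape)
        return self.transform.center_of(rows, cols)

    def copy_with(self, data: np.ndarray, name: str | None = None) -> "RasterGrid":
        return replace(self, data=data, name=name or self.name)


@dataclass
class RasterStack:
    """Named, aligned single-band layers sharing one geotransform."""

    layers: dict[str, np.ndarray]
    transform: GridTransform
    _shape: tuple[int, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"stack layers disagree on shape: {shapes}")
        self._shape = next(iter(shapes)) if shapes else (0, 0)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> RasterGrid:
        return RasterGrid(self.layers[name], self.transform, name=name)

    def add(self, name: str, data: np.ndarray) -> None:
        data = np.asarray(data)
        if self.layers and data.shape != self.shape:
            raise ValueError(f"layer {name!r} shape {data.shape} != stack {self.shape}")
        self.layers[name] = data
        self._shape = data.shape

    def subset(self, names: list[str]) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing stack layers: {missing}")
        return RasterStack({n: self.layers[n] for n in names}, self.transform)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        """(n_layers, nrow, ncol) float array in the given band order."""
        names = names or self.names
        return np.stack([np.asarray(self.layers[n], dtype=float) for n in names])

    def values_at(self, x, y, names: list[str] | None = None) -> np.ndarray:
        """(n_points, n_layers) matrix of cell values at point locations."""
        names = names or self.names
        cols = [self[n].values_at(x, y) for n in names]
        return np.column_stack(cols) if cols else np.empty((np.size(x), 0))
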