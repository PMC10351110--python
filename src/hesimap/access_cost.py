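"""Least-cost travel time to the nearest health facility.

The friction raster gives traversal cost in minutes per metre. Travel
time is a multi-source exact Dijkstra over the 8-connected cell graph:
the cost of stepping between adjacent cells is the mean of their two
friction values times the step length (cell_size, or cell_size * sqrt(2)
on diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import RasterGrid

__all__ = ["FrictionSurface", "TravelTimeLayer", "travel_time", "extract_at_points"]


@dataclass
class FrictionSurface:
    grid: RasterGrid
    mode: str  # "walk" | "drive"

    def __post_init__(self) -> None:
        if self.mode not in ("walk", "drive"):
            raise ValueError(f"mode must be walk or drive, got {self.mode!r}")
        valid = self.grid.data[~self.grid.mask]
        if valid.size and (valid <= 0).any():
            raise ValueError("friction values must be > 0 (minutes per metre)")


@dataclass
class TravelTimeLayer:
    grid: RasterGrid  # minutes to nearest facility
    mode: str


def _edge_graph(friction: np.ndarray, mask: np.ndarray, cell_size: float) -> coo_matrix:
    nrow, ncol = friction.shape
    n = nrow * ncol
    idx = np.arange(n).reshape(nrow, ncol)
    # each undirected edge emitted once: down, right, down-right, down-left
    pairs = [
        (idx[:-1, :], idx[1:, :], 1.0),
        (idx[:, :-1], idx[:, 1:], 1.0),
        (idx[:-1, :-1], idx[1:, 1:], np.sqrt(2.0)),
        (idx[:-1, 1:], idx[1:, :-1], np.sqrt(2.0)),
    ]
    flat_f, flat_m = friction.ravel(), mask.ravel()
    rows_i, cols_j, costs = [], [], []
    for src, dst, length in pairs:
        s, d = src.ravel(), dst.ravel()
        ok = ~flat_m[s] & ~flat_m[d]
        cost = 0.5 * (flat_f[s] + flat_f[d]) * length * cell_size
        rows_i.append(s[ok])
        cols_j.append(d[ok])
        costs.append(cost[ok])
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    c = np.concatenate(costs)
    return coo_matrix(
        (np.concatenate([c, c]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )


def travel_time(friction: FrictionSurface, facilities: pd.DataFrame) -> TravelTimeLayer:
    """Minutes from every cell to its nearest facility over the friction grid.

    ``facilities`` needs metric ``x``/``y`` columns. Facilities outside
    the grid raise; facilities all on nodata cells raise.
    """
    grid = friction.grid
    if len(facilities) == 0:
        raise ValueError("need at least one facility")
    row, col = grid.transform.cell_of(
        facilities["x"].to_numpy(), facilities["y"].to_numpy()
    )
    nrow, ncol = grid.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    if not inside.any():
        raise ValueError("no facility inside the grid")
    row, col = row[inside], col[inside]
    mask = grid.mask
    on_data = ~mask[row, col]
    if not on_data.any():
        raise ValueError("all facilities fall on nodata cells")
    sources = np.unique(row[on_data] * ncol + col[on_data])

    fric = np.where(mask, 1.0, grid.data.astype(float))
    graph = _edge_graph(fric, mask, grid.transform.cell_size).tocsr()
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    times = dist.reshape(grid.shape)
    times[mask] = np.nan
    return TravelTimeLayer(
        grid=grid.copy_with(times, name=f"travel_time_{friction.mode}"),
        mode=friction.mode,
    )


def extract_at_points(layer: RasterGrid, points: pd.DataFrame) -> np.ndarray:
    """Cell-value lookup at each point's containing cell (no smoothing)."""
    ids = points["id"] if "id" in points.columns else points.index
    return layer.values_at(
        points["x"].to_numpy(), points["y"].to_numpy(), ids=np.asarray(ids)
    )


def filter_facilities(
    facilities: pd.DataFrame, size_classes: list[str], column: str = "size_class"
) -> pd.DataFrame:
    """Keep facilities whose size class is in the given set (e.g. medium/large)."""
    if column not in facilities.columns:
        raise ValueError(f"facility table lacks {column!r} column")
    return facilities[facilities[column].isin(size_classes)].reset_index(drop=True)
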