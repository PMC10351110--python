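"""Zonal aggregation and heterogeneity analytics.

Aggregates hyperlocal layers to any zone-label raster and computes the
downstream summaries: per-zone population-weighted means and cell
ranges, range widths across aggregation levels, the Mean Cumulative
Score (nearest-integer mean of the three per-index range widths, half
away from zero), the prevalent-determinant categorical layer, tercile
population counts, and multi-criteria zone targeting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid, RasterStack

__all__ = [
    "McsResult",
    "zonal_aggregate",
    "range_summary",
    "mean_cumulative_score",
    "prevalent_determinant",
    "population_count",
    "select_zones",
    "DETERMINANT_PRIORITY",
]

# tie-break priority for the prevalent determinant (first wins)
DETERMINANT_PRIORITY = ("convenience", "complacency", "confidence")


@dataclass(frozen=True)
class McsResult:
    widths: tuple  # per-index range widths, points
    cumulative_score: float
    mcs: int


def zonal_aggregate(
    layers: RasterStack,
    zones: RasterGrid,
    population: RasterGrid | None = None,
) -> pd.DataFrame:
    """Per-zone, per-layer population-weighted mean and cell min/max.

    Empty zones (no valid cells) yield flagged rows with NaN statistics.
    """
    if layers.shape != zones.shape:
        raise ValueError("layers and zones are not aligned")
    labels = np.unique(zones.data[~zones.mask])
    pop = None
    if population is not None:
        if not zones.aligned_with(population):
            raise ValueError("population raster not aligned")
        pop = np.where(np.isnan(population.data), 0.0, population.data.astype(float))
    rows = []
    for label in labels:
        in_zone = zones.data == label
        row = {"zone": int(label)}
        zone_pop = pop[in_zone] if pop is not None else None
        row["population"] = float(zone_pop.sum()) if zone_pop is not None else float(
            in_zone.sum()
        )
        for name in layers.names:
            vals = np.asarray(layers.layers[name], dtype=float)[in_zone]
            ok = ~np.isnan(vals)
            if not ok.any():
                row[f"{name}_mean"] = np.nan
                row[f"{name}_min"] = np.nan
                row[f"{name}_max"] = np.nan
                row["flag"] = "empty_zone"
                continue
            w = zone_pop[ok] if zone_pop is not None else np.ones(ok.sum())
            if w.sum() == 0:
                w = np.ones(ok.sum())
            row[f"{name}_mean"] = float(np.average(vals[ok], weights=w))
            row[f"{name}_min"] = float(vals[ok].min())
            row[f"{name}_max"] = float(vals[ok].max())
        rows.append(row)
    out = pd.DataFrame(rows)
    if "flag" not in out.columns:
        out["flag"] = ""
    return out


def range_summary(values_per_level: dict) -> pd.DataFrame:
    """(min, max, width) per aggregation level from per-zone values.

    ``values_per_level`` maps a level name (e.g. "state") to the array of
    zone-level values of one index at that level.
    """
    rows = []
    for level, values in values_per_level.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError(f"level {level!r} has no values")
        rows.append(
            {"level": level, "min": float(arr.min()), "max": float(arr.max()),
             "width": float(arr.max() - arr.min())}
        )
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x != 0 else 0


def mean_cumulative_score(widths) -> McsResult:
    """Cumulative score (sum of the three per-index widths) and its
    nearest-integer mean, rounding half away from zero."""
    widths = tuple(float(w) for w in widths)
    if len(widths) != 3:
        raise ValueError(f"expected exactly three widths, got {len(widths)}")
    if any(w < 0 for w in widths):
        raise ValueError("range widths must be non-negative")
    cumulative = sum(widths)
    return McsResult(
        widths=widths,
        cumulative_score=cumulative,
        mcs=_round_half_away(cumulative / 3.0),
    )


def prevalent_determinant(
    confidence: RasterGrid,
    complacency: RasterGrid,
    convenience: RasterGrid,
    priority: tuple = DETERMINANT_PRIORITY,
) -> tuple[RasterGrid, dict]:
    """Cellwise dominant hesitancy barrier.

    Confidence and convenience are inverted (100 - score) so that higher
    always means a stronger barrier; the argmax of the three transformed
    layers wins, with ties broken by the declared priority order. Returns
    the label raster and its value -> name legend.
    """
    if not (confidence.aligned_with(complacency) and confidence.aligned_with(convenience)):
        raise ValueError("determinant layers are not aligned")
    transformed = {
        "confidence": 100.0 - confidence.data.astype(float),
        "complacency": complacency.data.astype(float),
        "convenience": 100.0 - convenience.data.astype(float),
    }
    order = list(priority)
    stack = np.stack([transformed[name] for name in order])
    nodata = np.isnan(stack).any(axis=0)
    # argmax over priority order: earlier layers win exact ties
    winner = np.argmax(np.where(np.isnan(stack), -np.inf, stack), axis=0)
    labels = winner.astype(np.int64)
    labels[nodata] = -1
    legend = {i: name for i, name in enumerate(order)}
    return (
        RasterGrid(labels, confidence.transform, name="prevalent_determinant"),
        legend,
    )


def population_count(
    share_layer: RasterGrid, population: RasterGrid, zones: RasterGrid
) -> pd.DataFrame:
    """Sum of share x population per zone (people in the tercile class)."""
    if not (share_layer.aligned_with(population) and share_layer.aligned_with(zones)):
        raise ValueError("rasters are not aligned")
    share = share_layer.data.astype(float)
    ok = ~np.isnan(share)
    if ((share[ok] < 0) | (share[ok] > 1)).any():
        raise ValueError("share layer has values outside [0, 1]")
    valid = ok & ~zones.mask & ~np.isnan(population.data.astype(float))
    counts = (
        pd.DataFrame(
            {
                "zone": zones.data[valid],
                "count": share[valid] * population.data[valid].astype(float),
            }
        )
        .groupby("zone")["count"]
        .sum()
        .reset_index()
    )
    return counts


def select_zones(zone_stats: pd.DataFrame, criteria: list) -> list:
    """Zones satisfying ALL ``(column, comparator, threshold)`` criteria.

    Comparators: ">", ">=", "<", "<=", "==". Ordering is by zone id.
    """
    ops = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
        "==": np.equal,
    }
    mask = np.ones(len(zone_stats), dtype=bool)
    for column, comparator, threshold in criteria:
        if column not in zone_stats.columns:
            raise ValueError(f"unknown layer/column {column!r} in criteria")
        if comparator not in ops:
            raise ValueError(f"unknown comparator {comparator!r}")
        mask &= ops[comparator](zone_stats[column].to_numpy(dtype=float), threshold)
    return sorted(zone_stats.loc[mask, "zone"].tolist())
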