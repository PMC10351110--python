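"""Survey-vs-raster validation at the survey's level of representativeness.

For each admin zone: the weighted survey mean with a cluster-bootstrap
95% CI, the population-weighted raster mean, their absolute difference,
and whether the raster mean falls inside the survey CI. Overall pass
requires every zone with a defined CI to contain its raster mean;
failing zones are carried forward as caution flags, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid

__all__ = ["ValidationReport", "survey_zone_mean_ci", "validate_layer"]


@dataclass
class ValidationReport:
    table: pd.DataFrame  # zone, survey_mean, ci_low, ci_high, raster_mean, abs_diff, within_ci, flag
    passed: bool
    failing_zones: list


def survey_zone_mean_ci(
    survey: pd.DataFrame,
    weights: np.ndarray,
    values: np.ndarray,
    zone_col: str,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-zone weighted mean and 95% cluster-bootstrap CI.

    ``values`` is the per-respondent numeric variable, aligned to the
    survey rows. Zones with a single cluster get a flagged, undefined CI;
    empty zones are flagged rows, not errors.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "zone": survey[zone_col].to_numpy(),
            "cluster": survey["cluster_id"].to_numpy(),
            "w": np.asarray(weights, dtype=float),
            "v": np.asarray(values, dtype=float),
        }
    ).dropna(subset=["v"])
    rows = []
    for zone, g in df.groupby("zone", sort=True):
        if g.empty:
            rows.append({"zone": zone, "survey_mean": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "flag": "no_respondents"})
            continue
        mean = np.average(g["v"], weights=g["w"])
        clusters = g["cluster"].unique()
        if len(clusters) < 2:
            rows.append({"zone": zone, "survey_mean": mean, "ci_low": np.nan,
                         "ci_high": np.nan, "flag": "single_cluster_ci_undefined"})
            continue
        # resampling clusters only permutes per-cluster weighted sums
        sums = g.assign(wv=g["w"] * g["v"]).groupby("cluster")[["wv", "w"]].sum()
        wv = sums["wv"].to_numpy()
        wsum = sums["w"].to_numpy()
        k = len(clusters)
        picks = rng.integers(0, k, size=(n_boot, k))
        boot_means = wv[picks].sum(axis=1) / wsum[picks].sum(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        # the point estimate is kept inside the interval by construction
        rows.append({"zone": zone, "survey_mean": mean,
                     "ci_low": min(lo, mean), "ci_high": max(hi, mean), "flag": ""})
    return pd.DataFrame(rows)


def zone_raster_means(
    layer: RasterGrid,
    zones: RasterGrid,
    population: RasterGrid | None = None,
) -> pd.DataFrame:
    """Population-weighted (or plain) mean of a raster within each zone."""
    if not layer.aligned_with(zones):
        raise ValueError("layer and zones are not aligned")
    if population is not None and not layer.aligned_with(population):
        raise ValueError("population raster not aligned")
    valid = ~layer.mask & ~zones.mask
    vals = layer.data[valid].astype(float)
    labels = zones.data[valid]
    pop = (
        np.ones_like(vals)
        if population is None
        else np.where(np.isnan(population.data[valid]), 0.0,
                      population.data[valid].astype(float))
    )
    out = (
        pd.DataFrame({"zone": labels, "v": vals, "p": pop})
        .assign(vp=lambda d: d["v"] * d["p"])
        .groupby("zone")
        .agg(vp=("vp", "sum"), p=("p", "sum"))
    )
    out["raster_mean"] = out["vp"] / out["p"]
    return out[["raster_mean"]].reset_index()


def validate_layer(
    layer: RasterGrid,
    population: RasterGrid | None,
    zones: RasterGrid,
    survey_stats: pd.DataFrame,
) -> ValidationReport:
    """Compare per-zone raster means against survey means and their CIs."""
    raster = zone_raster_means(layer, zones, population)
    merged = survey_stats.merge(raster, on="zone", how="left")
    missing = merged.loc[
        merged["raster_mean"].isna() & merged["survey_mean"].notna(), "zone"
    ]
    if len(missing):
        raise ValueError(f"zones absent from raster: {list(missing)}")
    merged["abs_diff"] = (merged["survey_mean"] - merged["raster_mean"]).abs()
    has_ci = merged["ci_low"].notna() & merged["ci_high"].notna()
    merged["within_ci"] = has_ci & (
        (merged["raster_mean"] >= merged["ci_low"])
        & (merged["raster_mean"] <= merged["ci_high"])
    )
    failing = merged.loc[has_ci & ~merged["within_ci"], "zone"].tolist()
    merged.loc[merged["zone"].isin(failing), "flag"] = "outside_survey_ci"
    passed = len(failing) == 0
    return ValidationReport(table=merged, passed=passed, failing_zones=failing)
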