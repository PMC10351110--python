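"""Configuration-driven orchestration of the full pipeline.

Stages communicate only through written artifacts (CSV/GeoTIFF/JSON) in
the output directory, in dependency order:

    simulate -> weight -> access -> index -> interpolate -> validate -> analyze

A failing validation produces a completed run with caution flags (exit
status 2 at the CLI), not a crash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .access_cost import FrictionSurface, extract_at_points, filter_facilities, travel_time
from .grids import RasterGrid, RasterStack
from .mca_indices import (
    IndexSpec,
    bin_continuous,
    composite_convenience,
    driver_correlations,
    fit_mca,
    mca_diagnostics,
    score_index,
)
from .layer_validation import survey_zone_mean_ci, validate_layer
from .spatial_interp import (
    DEFAULT_POOL,
    LEARNER_REGISTRY,
    TargetSpec,
    renormalize_terciles,
    two_stage_interpolate,
)
from .survey_weighting import ipf_rake
from .synthetic_world import SyntheticWorld, WorldConfig, generate_world, read_world, write_world
from .zonal_analysis import (
    mean_cumulative_score,
    population_count,
    prevalent_determinant,
    zonal_aggregate,
)

log = logging.getLogger(__name__)

DETERMINANTS = ("confidence", "complacency", "convenience")


def default_index_specs() -> dict:
    """Index definitions mirroring the selected-inputs table: four fitted
    MCAs, with convenience assembled later as a composite."""
    return {
        "confidence": IndexSpec(
            name="confidence",
            inputs=("vax_unsafe", "vax_ineffective", "vax_weak_new_strains",
                    "trusted_not_vaccinated"),
            anchor=("vax_unsafe", -1),
        ),
        "complacency": IndexSpec(
            name="complacency",
            inputs=("no_risk_friends_family", "healthy_no_worry",
                    "not_spreading_local", "covid_not_real", "had_covid_no_fear"),
            anchor=("no_risk_friends_family", 1),
        ),
        "accessibility": IndexSpec(
            name="accessibility",
            inputs=("walk_time_bin", "drive_time_bin", "owns_scooter"),
            anchor=("walk_time_bin", -1),
        ),
        "time_financial": IndexSpec(
            name="time_financial",
            inputs=("supply_concern", "unknown_vax_location", "no_time",
                    "cost_concern"),
            anchor=("unknown_vax_location", -1),
        ),
    }


@dataclass
class PipelineConfig:
    world: WorldConfig = dc_field(default_factory=WorldConfig)
    seed: int = 0
    k_folds: int = 5
    learner_pool: tuple = DEFAULT_POOL
    n_boot: int = 300
    ipf_tol: float = 1e-6
    ipf_max_iter: int = 100
    travel_bins: int = 3
    facility_size_classes: tuple = ("medium", "large")
    stage1_targets: tuple = ("asset_owner", "owns_radio")
    tercile_index: str = "confidence"  # whose terciles get interpolated
    targeting_criteria: tuple = ()  # (column, comparator, threshold) triples

    def __post_init__(self) -> None:
        unknown = [l for l in self.learner_pool if l not in LEARNER_REGISTRY]
        if unknown:
            raise ValueError(f"unknown learner name(s) in learner_pool: {unknown}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = hio.read_yaml(path) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config field(s): {sorted(bad)}")
        if "world" in raw:
            raw["world"] = WorldConfig(**raw["world"])
        for key in ("learner_pool", "stage1_targets", "facility_size_classes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "targeting_criteria" in raw:
            raw["targeting_criteria"] = tuple(tuple(c) for c in raw["targeting_criteria"])
        return cls(**raw)


def stage_simulate(config: PipelineConfig, outdir: Path) -> SyntheticWorld:
    world = generate_world(config.world)
    write_world(world, outdir / "world")
    return world


def stage_weight(config: PipelineConfig, world: SyntheticWorld, outdir: Path) -> np.ndarray:
    result = ipf_rake(world.survey, world.margins, tol=config.ipf_tol,
                      max_iter=config.ipf_max_iter)
    if not result.converged:
        log.warning("IPF did not converge: max margin error %.3g",
                    result.max_margin_error)
    out = world.survey[["respondent_id"]].copy()
    out["weight"] = result.weights
    hio.write_table(outdir / "weights.csv", out)
    hio.write_json(outdir / "weights_meta.json", {
        "iterations": result.iterations,
        "max_margin_error": result.max_margin_error,
        "converged": result.converged,
    })
    return result.weights


def stage_access(config: PipelineConfig, world: SyntheticWorld, outdir: Path,
                 weights: np.ndarray) -> pd.DataFrame:
    """Travel times to medium/large facilities, attached to the survey as
    weighted-quantile bins."""
    facilities = filter_facilities(world.facilities,
                                   list(config.facility_size_classes))
    survey = world.survey.copy()
    for mode, grid in (("walk", world.friction_walk), ("drive", world.friction_drive)):
        layer = travel_time(FrictionSurface(grid, mode), facilities)
        hio.write_raster(outdir / f"travel_time_{mode}.tif", layer.grid)
        minutes = extract_at_points(layer.grid, survey.rename(
            columns={"respondent_id": "id"}))
        survey[f"{mode}_time_min"] = minutes
        survey[f"{mode}_time_bin"] = bin_continuous(
            minutes, weights, n_bins=config.travel_bins, prefix="t"
        )
    hio.write_table(outdir / "survey_access.csv", survey)
    return survey


def stage_index(config: PipelineConfig, survey: pd.DataFrame, outdir: Path,
                weights: np.ndarray) -> pd.DataFrame:
    """Fit the four MCAs, build the composite convenience index, attach
    scores and terciles to the survey, and write driver/diagnostic reports."""
    specs = default_index_specs()
    scores, diagnostics, drivers = {}, [], []
    for name, spec in specs.items():
        model = fit_mca(survey, spec, weights)
        s = score_index(survey, model)
        scores[name] = s
        diagnostics.append(mca_diagnostics(model))
        rep = driver_correlations(survey, s, spec, weights)
        rep.insert(0, "index", name)
        drivers.append(rep)

    conv = composite_convenience(scores["accessibility"], scores["time_financial"],
                                 weights)
    scores["convenience"] = conv

    out = survey.copy()
    for name, s in scores.items():
        out.loc[s.index, f"{name}_score"] = s.score_0_100
        out.loc[s.index, f"{name}_tercile"] = s.tercile
    hio.write_table(outdir / "survey_indexed.csv", out)
    hio.write_table(outdir / "driver_correlations.csv", pd.concat(drivers))
    hio.write_json(outdir / "mca_diagnostics.json", diagnostics)
    return out


def stage_interpolate(config: PipelineConfig, world: SyntheticWorld,
                      survey: pd.DataFrame, outdir: Path,
                      weights: np.ndarray) -> dict:
    stage1 = [TargetSpec(name=f"s1_{c}", column=c, kind="share", level="yes")
              for c in config.stage1_targets]
    stage2 = [TargetSpec(name=f"{d}_score", column=f"{d}_score", kind="score")
              for d in DETERMINANTS]
    ti = config.tercile_index
    stage2 += [
        TargetSpec(name=f"{ti}_{lvl}_share", column=f"{ti}_tercile",
                   kind="share", level=lvl)
        for lvl in ("low", "mid", "high")
    ]
    layers, models = two_stage_interpolate(
        survey, weights, stage1, stage2, world.covariates,
        learner_pool=config.learner_pool, k_folds=config.k_folds,
        seed=config.seed,
    )
    low, mid, high = (layers[f"{ti}_{lvl}_share"] for lvl in ("low", "mid", "high"))
    low, mid, high = renormalize_terciles(low, mid, high)
    layers[f"{ti}_low_share"], layers[f"{ti}_mid_share"], layers[f"{ti}_high_share"] = (
        low, mid, high,
    )
    for name, layer in layers.items():
        hio.write_raster(outdir / f"layer_{name}.tif", layer.grid)
    hio.write_json(outdir / "model_cards.json",
                   {name: m.card() for name, m in models.items()})
    return layers


def stage_validate(config: PipelineConfig, world: SyntheticWorld,
                   survey: pd.DataFrame, layers: dict, outdir: Path,
                   weights: np.ndarray) -> dict:
    reports, all_passed = {}, True
    for d in DETERMINANTS:
        values = survey[f"{d}_score"].to_numpy(dtype=float) / 100.0
        stats_ = survey_zone_mean_ci(survey, weights, values, "state_id",
                                     n_boot=config.n_boot, seed=config.seed)
        report = validate_layer(layers[f"{d}_score"].grid, world.population,
                                world.state_zones, stats_)
        report.table.insert(0, "index", d)
        reports[d] = report
        all_passed &= report.passed
    table = pd.concat([r.table for r in reports.values()])
    hio.write_table(outdir / "validation.csv", table)
    hio.write_json(outdir / "validation_summary.json", {
        "passed": all_passed,
        "failing_zones": {d: r.failing_zones for d, r in reports.items()},
    })
    return {"passed": all_passed, "reports": reports}


def stage_analyze(config: PipelineConfig, world: SyntheticWorld, layers: dict,
                  outdir: Path) -> dict:
    # analysis is on the paper's 0-100 index-point scale
    score_stack = RasterStack(
        {d: layers[f"{d}_score"].grid.data * 100.0 for d in DETERMINANTS},
        world.transform,
    )
    state_stats = zonal_aggregate(score_stack, world.state_zones, world.population)
    lga_stats = zonal_aggregate(score_stack, world.lga_zones, world.population)
    hio.write_table(outdir / "zone_stats_state.csv", state_stats)
    hio.write_table(outdir / "zone_stats_lga.csv", lga_stats)

    # range widths per index across aggregation levels
    ranges = []
    for d in DETERMINANTS:
        cells = score_stack.layers[d]
        ranges.append({
            "index": d,
            "state_width": state_stats[f"{d}_mean"].max() - state_stats[f"{d}_mean"].min(),
            "lga_width": lga_stats[f"{d}_mean"].max() - lga_stats[f"{d}_mean"].min(),
            "hyperlocal_width": float(np.nanmax(cells) - np.nanmin(cells)),
        })
    ranges_df = pd.DataFrame(ranges)
    hio.write_table(outdir / "range_summary.csv", ranges_df)

    # per-state MCS at LGA and hyperlocal levels
    lga_state = {}  # lga label -> state label
    for lga in np.unique(world.lga_zones.data):
        states = world.state_zones.data[world.lga_zones.data == lga]
        lga_state[int(lga)] = int(np.bincount(states).argmax())
    mcs_rows = []
    for state in sorted(state_stats["zone"]):
        member_lgas = [l for l, s in lga_state.items() if s == state]
        sub = lga_stats[lga_stats["zone"].isin(member_lgas)]
        in_state = world.state_zones.data == state
        for level, widths in (
            ("lga", [sub[f"{d}_mean"].max() - sub[f"{d}_mean"].min()
                     for d in DETERMINANTS]),
            ("hyperlocal", [float(np.nanmax(score_stack.layers[d][in_state])
                            - np.nanmin(score_stack.layers[d][in_state]))
                            for d in DETERMINANTS]),
        ):
            res = mean_cumulative_score(widths)
            mcs_rows.append({
                "state": state, "level": level,
                **{f"{d}_width": w for d, w in zip(DETERMINANTS, res.widths)},
                "cumulative_score": res.cumulative_score, "mcs": res.mcs,
            })
    hio.write_table(outdir / "mcs_by_state.csv", pd.DataFrame(mcs_rows))

    prev, legend = prevalent_determinant(
        score_stack["confidence"], score_stack["complacency"],
        score_stack["convenience"],
    )
    hio.write_raster(outdir / "prevalent_determinant.tif", prev)
    hio.write_json(outdir / "prevalent_determinant_legend.json", legend)

    ti = config.tercile_index
    counts = population_count(layers[f"{ti}_low_share"].grid, world.population,
                              world.lga_zones)
    counts = counts.rename(columns={"count": f"low_{ti}_population"})
    hio.write_table(outdir / f"low_{ti}_population_by_lga.csv", counts)

    targeting = None
    if config.targeting_criteria:
        from .zonal_analysis import select_zones

        share_stats = zonal_aggregate(
            RasterStack(
                {f"{ti}_low_share": layers[f"{ti}_low_share"].grid.data},
                world.transform,
            ),
            world.lga_zones,
            world.population,
        )
        merged = lga_stats.merge(share_stats.drop(columns=["population", "flag"]),
                                 on="zone")
        targeting = select_zones(merged, list(config.targeting_criteria))
        hio.write_table(outdir / "targeting.csv",
                        pd.DataFrame({"zone": targeting}))
    return {"ranges": ranges_df, "mcs": pd.DataFrame(mcs_rows), "targeting": targeting}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns a summary dict with
    ``exit_code`` 0 (pass) or 2 (validation caution)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings, t0 = {}, time.perf_counter()

    def _mark(stage: str) -> None:
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    world = stage_simulate(config, outdir)
    _mark("simulate")
    weights = stage_weight(config, world, outdir)
    _mark("weight")
    survey = stage_access(config, world, outdir, weights)
    _mark("access")
    survey = stage_index(config, survey, outdir, weights)
    _mark("index")
    layers = stage_interpolate(config, world, survey, outdir, weights)
    _mark("interpolate")
    validation = stage_validate(config, world, survey, layers, outdir, weights)
    _mark("validate")
    stage_analyze(config, world, layers, outdir)
    _mark("analyze")

    summary = {
        "seed": config.seed,
        "world_seed": config.world.seed,
        "n_respondents": len(survey),
        "validation_passed": bool(validation["passed"]),
        "exit_code": 0 if validation["passed"] else 2,
        "timings_s": timings,
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def load_world_dir(path: str | Path) -> SyntheticWorld:
    return read_world(Path(path) / "world")
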