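"""Self-contained synthetic country with known ground truth.

Generates, from a single seed: smoothed Gaussian-random-field covariate
rasters; rectangular state/LGA zone partitions; friction surfaces and
facility locations; a population raster; latent determinant propensity
fields that are linear in the covariates plus spatial noise; true 0-100
index surfaces; and a clustered categorical household survey whose item
responses are drawn from ordered-logistic / Bernoulli models of the
cell-level latents, so every downstream stage has recoverable signal.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as hio
from .grids import GridTransform, RasterGrid, RasterStack
from .survey_weighting import MarginSpec

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "write_world",
    "read_world",
    "world_digest",
    "response_probabilities",
    "CONSTRUCTS",
    "ITEMS",
]

# latent constructs; confidence/accessibility/time_financial latents are
# concern/barrier propensities (higher = worse), complacency is direct
CONSTRUCTS = ("confidence", "complacency", "accessibility", "time_financial")


@dataclass(frozen=True)
class ItemDef:
    name: str
    construct: str
    levels: tuple  # ordered category labels, low to high concern/agreement
    alpha: float  # discrimination on the standardized cell latent
    cum_targets: tuple  # national cumulative probabilities for levels[:-1]


_AGREE4 = ("1_strongly_disagree", "2_disagree", "3_agree", "4_strongly_agree")
_AGREE3 = ("1_disagree", "2_neutral", "3_agree")
_YESNO = ("no", "yes")

ITEMS: tuple[ItemDef, ...] = (
    # concerns about receiving the vaccine (confidence determinant)
    ItemDef("vax_unsafe", "confidence", _AGREE4, 1.6, (0.30, 0.55, 0.85)),
    ItemDef("vax_ineffective", "confidence", _AGREE4, 1.5, (0.35, 0.60, 0.88)),
    ItemDef("vax_weak_new_strains", "confidence", _AGREE4, 1.3, (0.30, 0.62, 0.86)),
    ItemDef("trusted_not_vaccinated", "confidence", _YESNO, 1.2, (0.60,)),
    # feelings about disease spread (complacency determinant)
    ItemDef("no_risk_friends_family", "complacency", _AGREE3, 1.6, (0.35, 0.70)),
    ItemDef("healthy_no_worry", "complacency", _AGREE3, 1.5, (0.40, 0.72)),
    ItemDef("not_spreading_local", "complacency", _AGREE3, 1.3, (0.38, 0.70)),
    ItemDef("covid_not_real", "complacency", _YESNO, 1.1, (0.72,)),
    ItemDef("had_covid_no_fear", "complacency", _YESNO, 1.0, (0.70,)),
    # accessibility barriers (scooter ownership lowers the barrier)
    ItemDef("owns_scooter", "accessibility", _YESNO, -1.2, (0.65,)),
    # time and financial burdens
    ItemDef("supply_concern", "time_financial", _YESNO, 1.4, (0.55,)),
    ItemDef("unknown_vax_location", "time_financial", _YESNO, 1.5, (0.62,)),
    ItemDef("no_time", "time_financial", _YESNO, 1.3, (0.65,)),
    ItemDef("cost_concern", "time_financial", _AGREE3, 1.6, (0.40, 0.75)),
)

# spatially structured demographic/socioeconomic columns: covariate row
# used for the latent, discrimination, national prevalence of "yes"
_DEMOGRAPHICS = {
    "asset_owner": (1, 1.2, 0.40),
    "owns_radio": (2, 1.0, 0.65),
}


def _default_effect_matrix(n_covariates: int) -> np.ndarray:
    """Sparse deterministic loadings; covariate 0 acts as urbanicity."""
    eff = np.zeros((len(CONSTRUCTS), n_covariates))
    loadings = {
        "confidence": {0: -0.8, 1: 0.9, 2: 0.6},
        "complacency": {0: 0.7, 3: 0.8, 4: -0.5},
        "accessibility": {0: -1.0, 5: 0.8, 6: 0.5},
        "time_financial": {0: -0.5, 7: 0.9, 8: 0.4},
    }
    for i, construct in enumerate(CONSTRUCTS):
        for j, v in loadings[construct].items():
            if j < n_covariates:
                eff[i, j] = v
    return eff


@dataclass
class WorldConfig:
    grid_width: int = 60
    grid_height: int = 60
    cell_size: float = 1000.0  # metres; 1 km^2 cells
    n_states: int = 3
    lgas_per_state: int = 4
    n_clusters: int = 150
    respondents_per_cluster: int = 30
    n_covariates: int = 12
    covariate_smoothness: float = 6.0  # correlation length in cells
    effect_matrix: np.ndarray | None = None
    noise_sd: float = 0.3
    n_facilities: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "grid_width", "grid_height", "n_states", "lgas_per_state",
            "n_clusters", "respondents_per_cluster", "n_covariates",
            "n_facilities",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_states * self.lgas_per_state > self.grid_width * self.grid_height:
            raise ValueError("more zones than grid cells")
        if self.n_clusters > self.grid_width * self.grid_height:
            raise ValueError("more clusters than grid cells")
        if self.effect_matrix is None:
            self.effect_matrix = _default_effect_matrix(self.n_covariates)
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (len(CONSTRUCTS), self.n_covariates):
            raise ValueError(
                f"effect_matrix must be {(len(CONSTRUCTS), self.n_covariates)}"
            )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["effect_matrix"] = self.effect_matrix.tolist()
        return d


@dataclass
class SyntheticWorld:
    config: WorldConfig
    covariates: RasterStack
    state_zones: RasterGrid
    lga_zones: RasterGrid
    friction_walk: RasterGrid
    friction_drive: RasterGrid
    facilities: pd.DataFrame
    population: RasterGrid
    truth_indices: RasterStack  # confidence / complacency / convenience, 0-100
    latents: dict  # construct -> standardized cell field
    survey: pd.DataFrame
    margins: list = field(default_factory=list)

    @property
    def transform(self) -> GridTransform:
        return self.covariates.transform


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    """Unit-variance Gaussian random field: white noise, Gaussian kernel."""
    noise = rng.standard_normal(shape)
    if smoothness > 0:
        noise = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _standardize(fieldarr: np.ndarray) -> np.ndarray:
    sd = fieldarr.std()
    if sd == 0:
        return np.zeros_like(fieldarr)
    return (fieldarr - fieldarr.mean()) / sd


def _minmax_0_100(fieldarr: np.ndarray) -> np.ndarray:
    lo, hi = fieldarr.min(), fieldarr.max()
    if hi <= lo:
        return np.full_like(fieldarr, 50.0)
    return 100.0 * (fieldarr - lo) / (hi - lo)


def _zone_partition(shape, n_states: int, lgas_per_state: int):
    """States as column bands, LGAs as row sub-bands within each state."""
    nrow, ncol = shape
    states = np.zeros(shape, dtype=np.int64)
    lgas = np.zeros(shape, dtype=np.int64)
    col_edges = np.linspace(0, ncol, n_states + 1).astype(int)
    row_edges = np.linspace(0, nrow, lgas_per_state + 1).astype(int)
    for s in range(n_states):
        sl = slice(col_edges[s], col_edges[s + 1])
        states[:, sl] = s
        for k in range(lgas_per_state):
            lgas[row_edges[k]: row_edges[k + 1], sl] = s * lgas_per_state + k
    return states, lgas


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _item_level_probs(item: ItemDef, latent_z: np.ndarray) -> np.ndarray:
    """(n_levels, ...) category probabilities from the ordered-logistic link."""
    taus = np.array([np.log(c / (1 - c)) for c in item.cum_targets])
    cum = _sigmoid(taus[:, None] - item.alpha * latent_z.ravel()[None, :])
    cum = np.vstack([cum, np.ones((1, latent_z.size))])
    probs = np.diff(cum, axis=0, prepend=0.0)
    return probs.reshape((len(item.levels),) + latent_z.shape)


def response_probabilities(world: SyntheticWorld, item_name: str) -> np.ndarray:
    """Generator-truth per-cell category probabilities for one survey item."""
    item = next(i for i in ITEMS if i.name == item_name)
    return _item_level_probs(item, world.latents[item.construct])


def generate_world(config: WorldConfig) -> SyntheticWorld:
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_height, config.grid_width)
    transform = GridTransform(0.0, config.grid_height * config.cell_size,
                              config.cell_size)

    # covariate stack: independent smoothed Gaussian random fields
    cov_fields = np.stack(
        [_smooth_field(rng, shape, config.covariate_smoothness)
         for _ in range(config.n_covariates)]
    )
    covariates = RasterStack(
        {f"cov{j:02d}": cov_fields[j] for j in range(config.n_covariates)}, transform
    )

    if not np.any(config.effect_matrix):
        warnings.warn("effect_matrix is all zeros; generated world has no "
                      "covariate-driven signal", stacklevel=2)

    # latent propensity fields: linear in covariates plus smoothed noise
    latents = {}
    for i, construct in enumerate(CONSTRUCTS):
        lin = np.tensordot(config.effect_matrix[i], cov_fields, axes=1)
        if config.noise_sd > 0:
            lin = lin + config.noise_sd * _smooth_field(
                rng, shape, config.covariate_smoothness / 2
            )
        latents[construct] = _standardize(lin)

    access_barrier = _standardize(
        latents["accessibility"] + latents["time_financial"]
    )
    truth = RasterStack(
        {
            "confidence": 100.0 - _minmax_0_100(latents["confidence"]),
            "complacency": _minmax_0_100(latents["complacency"]),
            "convenience": 100.0 - _minmax_0_100(access_barrier),
        },
        transform,
    )

    state_zones_arr, lga_zones_arr = _zone_partition(
        shape, config.n_states, config.lgas_per_state
    )
    state_zones = RasterGrid(state_zones_arr, transform, name="state")
    lga_zones = RasterGrid(lga_zones_arr, transform, name="lga")

    urbanicity = cov_fields[0]
    population = RasterGrid(
        100.0 * np.exp(_standardize(urbanicity)), transform, name="population"
    )

    # friction increases with the accessibility barrier latent
    barrier_z = latents["accessibility"]
    friction_walk = RasterGrid(
        0.012 * np.exp(0.4 * barrier_z), transform, name="friction_walk"
    )
    friction_drive = RasterGrid(
        0.0012 * np.exp(0.4 * barrier_z), transform, name="friction_drive"
    )

    # facilities: sampled cells, probability increasing in urbanicity
    p_fac = np.exp(1.5 * _standardize(urbanicity)).ravel()
    p_fac /= p_fac.sum()
    fac_cells = rng.choice(urbanicity.size, size=config.n_facilities,
                           replace=False, p=p_fac)
    frow, fcol = np.unravel_index(fac_cells, shape)
    fx, fy = transform.center_of(frow, fcol)
    size_class = rng.choice(["small", "medium", "large"],
                            size=config.n_facilities, p=[0.3, 0.45, 0.25])
    if not np.isin(size_class, ["medium", "large"]).any():
        size_class[0] = "medium"
    facilities = pd.DataFrame(
        {"id": [f"fac{i:03d}" for i in range(config.n_facilities)],
         "x": fx, "y": fy, "size_class": size_class}
    )

    # survey: clusters are population-weighted sampled cells, centroids at
    # cell centres (no displacement)
    p_clu = population.data.ravel() / population.data.sum()
    clu_cells = rng.choice(population.data.size, size=config.n_clusters,
                           replace=False, p=p_clu)
    crow, ccol = np.unravel_index(clu_cells, shape)
    cx, cy = transform.center_of(crow, ccol)

    m = config.respondents_per_cluster
    n = config.n_clusters * m
    rep = np.repeat(np.arange(config.n_clusters), m)
    survey = pd.DataFrame(
        {
            "respondent_id": [f"r{i:05d}" for i in range(n)],
            "cluster_id": [f"c{k:04d}" for k in rep],
            "state_id": state_zones_arr[crow, ccol][rep],
            "lga_id": lga_zones_arr[crow, ccol][rep],
            "x": cx[rep],
            "y": cy[rep],
            "weight": 1.0,
        }
    )

    urban_cut = np.median(urbanicity)
    survey["urban"] = np.where(urbanicity[crow, ccol][rep] > urban_cut,
                               "urban", "rural")
    survey["gender"] = rng.choice(["female", "male"], size=n)
    cov_at = {j: cov_fields[j][crow, ccol][rep] for j in range(config.n_covariates)}
    demo_truth = {}
    for name, (j, alpha, prev) in _DEMOGRAPHICS.items():
        tau = np.log(prev / (1 - prev))
        p = _sigmoid(tau + alpha * _standardize(cov_fields[j])[crow, ccol][rep])
        survey[name] = np.where(rng.random(n) < p, "yes", "no")
        demo_truth[name] = _sigmoid(tau + alpha * _standardize(cov_fields[j]))

    for item in ITEMS:
        latent_at = latents[item.construct][crow, ccol][rep]
        probs = _item_level_probs(item, latent_at)  # (levels, n)
        u = rng.random(n)
        cum = np.cumsum(probs, axis=0)
        choice = (u[None, :] > cum).sum(axis=0)
        survey[item.name] = np.asarray(item.levels, dtype=object)[choice]

    # reference margins: truth population-weighted national shares
    popw = population.data / population.data.sum()
    urban_share = float(popw[urbanicity > urban_cut].sum())
    margins = [
        MarginSpec("urban", {"urban": urban_share, "rural": 1.0 - urban_share}),
        MarginSpec("gender", {"female": 0.5, "male": 0.5}),
    ]
    for name in _DEMOGRAPHICS:
        share = float((popw * demo_truth[name]).sum())
        margins.append(MarginSpec(name, {"yes": share, "no": 1.0 - share}))

    return SyntheticWorld(
        config=config,
        covariates=covariates,
        state_zones=state_zones,
        lga_zones=lga_zones,
        friction_walk=friction_walk,
        friction_drive=friction_drive,
        facilities=facilities,
        population=population,
        truth_indices=truth,
        latents=latents,
        survey=survey,
        margins=margins,
    )


def world_digest(world: SyntheticWorld) -> str:
    """SHA-256 over every array and table; equal seeds give equal digests."""
    h = hashlib.sha256()
    for name in world.covariates.names:
        h.update(world.covariates.layers[name].tobytes())
    for grid in (world.state_zones, world.lga_zones, world.friction_walk,
                 world.friction_drive, world.population):
        h.update(np.ascontiguousarray(grid.data).tobytes())
    for name in world.truth_indices.names:
        h.update(world.truth_indices.layers[name].tobytes())
    h.update(world.facilities.to_csv(index=False).encode())
    h.update(world.survey.to_csv(index=False).encode())
    return h.hexdigest()


def write_world(world: SyntheticWorld, directory: str | Path) -> dict:
    """Write the world as GeoTIFF / CSV / GeoJSON / JSON; returns a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _raster(key: str, grid: RasterGrid) -> None:
        path = directory / f"{key}.tif"
        hio.write_raster(path, grid)
        files[key] = path.name

    for name in world.covariates.names:
        _raster(name, world.covariates[name])
    _raster("state_zones", world.state_zones)
    _raster("lga_zones", world.lga_zones)
    _raster("friction_walk", world.friction_walk)
    _raster("friction_drive", world.friction_drive)
    _raster("population", world.population)
    for name in world.truth_indices.names:
        _raster(f"truth_{name}", world.truth_indices[name])

    hio.write_table(directory / "facilities.csv", world.facilities)
    files["facilities"] = "facilities.csv"
    hio.write_table(directory / "survey.csv", world.survey)
    files["survey"] = "survey.csv"

    margins_rows = [
        {"variable": m.variable, "category": cat, "target": t}
        for m in world.margins
        for cat, t in m.targets.items()
    ]
    hio.write_table(directory / "margins.csv", pd.DataFrame(margins_rows))
    files["margins"] = "margins.csv"

    for key, zones in (("state", world.state_zones), ("lga", world.lga_zones)):
        gj = hio.zones_to_geojson(zones)
        hio.write_geojson(directory / f"{key}_zones.geojson", gj)
        files[f"{key}_zones_geojson"] = f"{key}_zones.geojson"

    manifest = {
        "seed": world.config.seed,
        "config": world.config.to_jsonable(),
        "covariate_names": world.covariates.names,
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_world(directory: str | Path) -> SyntheticWorld:
    """Rebuild a world from :func:`write_world` output (latents are not
    persisted; truth surfaces and all pipeline inputs are)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["effect_matrix"] = np.asarray(cfg_d["effect_matrix"])
    config = WorldConfig(**cfg_d)
    files = manifest["files"]

    def _grid(key: str) -> RasterGrid:
        return hio.read_raster(directory / files[key], name=key)

    cov_layers = {n: _grid(n).data for n in manifest["covariate_names"]}
    first = hio.read_raster(directory / files[manifest["covariate_names"][0]])
    covariates = RasterStack(cov_layers, first.transform)
    truth = RasterStack(
        {n: _grid(f"truth_{n}").data
         for n in ("confidence", "complacency", "convenience")},
        first.transform,
    )
    margins_df = hio.read_table(directory / files["margins"])
    margins = [
        MarginSpec(var, dict(zip(g["category"], g["target"])))
        for var, g in margins_df.groupby("variable", sort=False)
    ]
    return SyntheticWorld(
        config=config,
        covariates=covariates,
        state_zones=_grid("state_zones"),
        lga_zones=_grid("lga_zones"),
        friction_walk=_grid("friction_walk"),
        friction_drive=_grid("friction_drive"),
        facilities=hio.read_table(directory / files["facilities"]),
        population=_grid("population"),
        truth_indices=truth,
        latents={},
        survey=hio.read_table(directory / files["survey"]),
        margins=margins,
    )
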