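# hesimap

Hyperlocal mapping of the WHO "3Cs" determinants of vaccine hesitancy
(confidence, complacency, convenience) from a georeferenced categorical
household survey to 1 km² grid-cell raster estimates.

The package implements the full analysis pipeline:

- **`synthetic_world`** — a self-contained synthetic country (covariate
  rasters as smoothed Gaussian random fields, state/LGA zone partitions,
  friction surfaces, facilities, population, and a clustered categorical
  survey drawn from known latent propensity fields) so every stage is
  testable against ground truth without any external data.
- **`survey_weighting`** — iterative proportional fitting (raking) of
  survey weights against reference marginal distributions.
- **`mca_indices`** — determinant indices via weighted Multiple
  Correspondence Analysis of the indicator matrix: anchor-aligned sign,
  0–100 min–max normalization, weighted tercile cutpoints, the composite
  convenience index (accessibility + time/financial burden), driver
  correlation tables, and raw / Benzécri-corrected inertia diagnostics.
- **`access_cost`** — exact multi-source Dijkstra least-cost walking and
  driving travel time to the nearest (medium/large) health facility over
  minutes-per-metre friction rasters; travel times enter the
  accessibility index after weighted-quantile binning.
- **`spatial_interp`** — cluster-level aggregates interpolated to the
  grid: correlation-ranked forward covariate selection with a 1-SE rule,
  a configurable learner pool (ridge / random forest / gradient boosting
  / kNN-on-coordinates) scored by cluster-grouped k-fold CV, ensembling
  of learners within one SE of the best, an all-covariate null-model
  check, and a two-stage scheme where demographic layers are predicted
  first and fed back as covariates for attitudinal targets.
- **`layer_validation`** — per-zone weighted survey means with
  cluster-bootstrap 95% CIs compared against population-weighted raster
  means; failing zones are carried forward as caution flags.
- **`zonal_analysis`** — population-weighted zonal statistics, range
  widths across aggregation levels, the Mean Cumulative Score, the
  prevalent-determinant layer, tercile population counts, and
  multi-criteria zone targeting.
- **`pipeline` / `cli`** — configuration-driven orchestration plus
  GeoTIFF / CSV / GeoJSON / YAML readers and writers.

## CLI

```bash
# full synthetic run (generate -> weight -> access -> index ->
# interpolate -> validate -> analyze)
hesimap run --config config.yaml --outdir out/

# or stage by stage (later stages read earlier stages' artifacts)
hesimap simulate --outdir out/
hesimap weight --outdir out/
hesimap access --outdir out/
hesimap index --outdir out/
hesimap interpolate --outdir out/
hesimap validate --outdir out/
hesimap analyze --outdir out/
```

Exit codes: 0 (pass), 2 (completed with validation cautions), 1 (error).
`--seed N` overrides every seed in the config. A minimal `config.yaml`:

```yaml
seed: 1
k_folds: 5
learner_pool: [ridge, random_forest, gradient_boosting, knn_coords]
world:
  grid_width: 60
  grid_height: 60
  n_states: 3
  lgas_per_state: 4
  n_clusters: 150
  respondents_per_cluster: 30
  seed: 1
```

Outputs include the written world (`world/`), `weights.csv`,
`survey_indexed.csv` (scores + terciles), `driver_correlations.csv`,
`mca_diagnostics.json`, per-target prediction rasters (`layer_*.tif`)
with model cards (`model_cards.json`: learner, covariates, CV RMSE,
null-model RMSE), `validation.csv`, zonal statistics, range summaries,
per-state MCS tables, and the prevalent-determinant raster.

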