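"""Cross-validated spatial interpolation of cluster-level survey aggregates.

Cluster aggregates (weighted index means rescaled to [0, 1], or weighted
tercile shares) are regressed on covariates sampled at cluster
centroids. Covariates are ranked by absolute weighted correlation with
the target and forward-selected on CV RMSE with a one-standard-error
stopping rule; every learner in the pool is then scored by k-fold CV
grouped at cluster level, and learners within one SE of the best are
averaged into the final ensemble. A null model (best learner on ALL
covariates) provides the covariate-selection sanity check. Attitudinal
targets can be interpolated in two stages: demographic/socioeconomic
layers are predicted first and fed back as extra covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grids import RasterGrid, RasterStack

__all__ = [
    "TargetSpec",
    "ClusterFrame",
    "InterpModel",
    "PredictedLayer",
    "LEARNER_REGISTRY",
    "build_cluster_frame",
    "select_model",
    "null_model_check",
    "predict_grid",
    "two_stage_interpolate",
    "renormalize_terciles",
]

log = logging.getLogger(__name__)

COORD_COLS = ("x", "y")


@dataclass(frozen=True)
class TargetSpec:
    """What to aggregate per cluster.

    kind "score" divides a 0-100 column by 100; "share" takes the
    weighted share of ``level`` within a categorical column; "mean"
    takes the weighted mean as-is.
    """

    name: str
    column: str
    kind: str = "mean"  # score | share | mean
    level: str | None = None
    bounds: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("score", "share", "mean"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "share" and self.level is None:
            raise ValueError("share targets need a level")


@dataclass
class ClusterFrame:
    """One row per cluster: centroid, n, target, covariates."""

    table: pd.DataFrame  # cluster_id, x, y, n, target, <covariate cols>
    target: str
    covariate_names: list


def _learner_ridge(seed: int):
    return make_pipeline(StandardScaler(), Ridge(alpha=1.0))


def _learner_rf(seed: int):
    return RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)


def _learner_gbm(seed: int):
    return GradientBoostingRegressor(random_state=seed)


def _learner_knn(seed: int):
    return KNeighborsRegressor(n_neighbors=5, weights="distance")


# knn_coords predicts from cluster coordinates, everything else from the
# selected covariate subset
LEARNER_REGISTRY = {
    "ridge": _learner_ridge,
    "random_forest": _learner_rf,
    "gradient_boosting": _learner_gbm,
    "knn_coords": _learner_knn,
}

DEFAULT_POOL = ("ridge", "random_forest", "gradient_boosting", "knn_coords")


@dataclass
class InterpModel:
    target: str
    learner: str  # single id or "ensemble(a+b)"
    members: list  # learner ids in the ensemble
    covariates: list
    cv_rmse: float
    cv_se: float
    null_rmse: float | None
    seed: int
    stage: int = 1
    fitted: dict = field(default_factory=dict, repr=False)
    bounds: tuple = (0.0, 1.0)

    def card(self) -> dict:
        return {
            "target": self.target,
            "learner": self.learner,
            "members": list(self.members),
            "covariates": list(self.covariates),
            "cv_rmse": self.cv_rmse,
            "cv_se": self.cv_se,
            "null_rmse": self.null_rmse,
            "seed": self.seed,
            "stage": self.stage,
        }


@dataclass
class PredictedLayer:
    grid: RasterGrid
    target: str
    bounds: tuple
    n_clipped: int = 0


def build_cluster_frame(
    survey: pd.DataFrame,
    weights: np.ndarray,
    target_spec: TargetSpec,
    covariates: RasterStack,
    values: np.ndarray | None = None,
) -> ClusterFrame:
    """Aggregate the target to cluster level and sample covariates there.

    ``values`` optionally supplies the per-respondent numeric target
    directly (already on its final scale), overriding column lookup —
    used for index scores that live outside the survey table.
    """
    df = survey[["cluster_id", "x", "y"]].copy()
    df["_w"] = np.asarray(weights, dtype=float)
    if values is not None:
        df["_v"] = np.asarray(values, dtype=float)
    elif target_spec.kind == "share":
        df["_v"] = (survey[target_spec.column] == target_spec.level).astype(float)
    elif target_spec.kind == "score":
        df["_v"] = survey[target_spec.column].astype(float) / 100.0
    else:
        df["_v"] = survey[target_spec.column].astype(float)
    df = df.dropna(subset=["_v"])
    if df.empty:
        raise ValueError(f"target {target_spec.name!r}: no non-missing respondents")

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "x": g["x"].iloc[0],
                "y": g["y"].iloc[0],
                "n": len(g),
                "target": np.average(g["_v"], weights=g["_w"]),
            }
        )

    agg = df.groupby("cluster_id", sort=True).apply(_agg, include_groups=False)
    agg = agg.reset_index()
    cov = covariates.values_at(agg["x"].to_numpy(), agg["y"].to_numpy())
    for j, name in enumerate(covariates.names):
        agg[name] = cov[:, j]
    return ClusterFrame(
        table=agg, target=target_spec.name, covariate_names=list(covariates.names)
    )


def _weighted_corr_rank(frame: ClusterFrame) -> list:
    t = frame.table
    w = t["n"].to_numpy(dtype=float)
    w = w / w.sum()
    y = t["target"].to_numpy(dtype=float)
    my = np.sum(w * y)
    scores = []
    for name in frame.covariate_names:
        x = t[name].to_numpy(dtype=float)
        mx = np.sum(w * x)
        cov = np.sum(w * (x - mx) * (y - my))
        vx = np.sum(w * (x - mx) ** 2)
        vy = np.sum(w * (y - my) ** 2)
        r = cov / np.sqrt(vx * vy) if vx > 0 and vy > 0 else 0.0
        scores.append((abs(r), name))
    return [name for _, name in sorted(scores, key=lambda p: (-p[0], p[1]))]


def _cv_predictions(
    frame: ClusterFrame, learner_id: str, cov_names: list, k_folds: int, seed: int
):
    """Out-of-fold predictions plus per-fold RMSEs; folds split clusters."""
    t = frame.table
    y = t["target"].to_numpy(dtype=float)
    X = (
        t[list(COORD_COLS)].to_numpy(dtype=float)
        if learner_id == "knn_coords"
        else t[cov_names].to_numpy(dtype=float)
    )
    if X.shape[1] == 0:
        X = np.zeros((len(t), 1))
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.full(len(t), np.nan)
    fold_rmse, fold_of = [], np.full(len(t), -1)
    for f, (tr, te) in enumerate(kf.split(X)):
        est = LEARNER_REGISTRY[learner_id](seed)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        oof[te] = pred
        fold_of[te] = f
        fold_rmse.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    return oof, np.array(fold_rmse), fold_of


def _rmse_se(y: np.ndarray, oof: np.ndarray, fold_rmse: np.ndarray):
    rmse = float(np.sqrt(np.mean((oof - y) ** 2)))
    se = float(fold_rmse.std(ddof=1) / np.sqrt(len(fold_rmse)))
    return rmse, se


def forward_select_covariates(
    frame: ClusterFrame,
    k_folds: int,
    seed: int,
    selection_learner: str = "ridge",
    max_covariates: int | None = None,
) -> list:
    """Greedy nested-subset search over correlation-ranked covariates,
    picking the smallest subset within one SE of the best CV RMSE."""
    ranked = _weighted_corr_rank(frame)
    if max_covariates is not None:
        ranked = ranked[:max_covariates]
    y = frame.table["target"].to_numpy(dtype=float)
    path = []
    for size in range(1, len(ranked) + 1):
        subset = ranked[:size]
        oof, fold_rmse, _ = _cv_predictions(
            frame, selection_learner, subset, k_folds, seed
        )
        rmse, se = _rmse_se(y, oof, fold_rmse)
        path.append((subset, rmse, se))
    best_rmse, best_se = min((p[1], p[2]) for p in path)
    for subset, rmse, _ in path:  # smallest subset within 1 SE of the best
        if rmse <= best_rmse + best_se:
            return subset
    return path[-1][0]


def select_model(
    frame: ClusterFrame,
    learner_pool: tuple = DEFAULT_POOL,
    k_folds: int = 5,
    seed: int = 0,
    covariate_subset: list | None = None,
    bounds: tuple = (0.0, 1.0),
    stage: int = 1,
) -> InterpModel:
    """Choose covariates, score the learner pool by grouped k-fold CV, and
    ensemble-average every learner within one SE of the best RMSE."""
    n_clusters = len(frame.table)
    if n_clusters < 2 * k_folds:
        raise ValueError(
            f"need >= {2 * k_folds} clusters for {k_folds}-fold CV, got {n_clusters}"
        )
    unknown = [l for l in learner_pool if l not in LEARNER_REGISTRY]
    if unknown:
        raise ValueError(f"unknown learners: {unknown}")

    subset = (
        covariate_subset
        if covariate_subset is not None
        else forward_select_covariates(frame, k_folds, seed)
    )
    y = frame.table["target"].to_numpy(dtype=float)

    results = {}
    for learner_id in learner_pool:
        try:
            oof, fold_rmse, _ = _cv_predictions(frame, learner_id, subset, k_folds, seed)
            rmse, se = _rmse_se(y, oof, fold_rmse)
            results[learner_id] = (rmse, se, oof)
        except Exception as exc:  # learner disqualified, not fatal
            log.warning("learner %s disqualified: %s", learner_id, exc)
    if not results:
        raise RuntimeError("every learner in the pool failed")

    # ties broken by declared pool order
    best_id = min(results, key=lambda l: (results[l][0], learner_pool.index(l)))
    best_rmse, best_se, _ = results[best_id]
    members = [l for l in learner_pool if l in results
               and results[l][0] <= best_rmse + best_se]
    if len(members) > 1:
        ens_oof = np.mean([results[l][2] for l in members], axis=0)
        cv_rmse = float(np.sqrt(np.mean((ens_oof - y) ** 2)))
        learner = "ensemble(" + "+".join(members) + ")"
    else:
        cv_rmse = best_rmse
        learner = members[0]

    fitted = {}
    for learner_id in members:
        X = (
            frame.table[list(COORD_COLS)].to_numpy(dtype=float)
            if learner_id == "knn_coords"
            else frame.table[subset].to_numpy(dtype=float)
        )
        if X.shape[1] == 0:
            X = np.zeros((len(frame.table), 1))
        est = LEARNER_REGISTRY[learner_id](seed)
        est.fit(X, y)
        fitted[learner_id] = est

    return InterpModel(
        target=frame.target,
        learner=learner,
        members=members,
        covariates=list(subset),
        cv_rmse=cv_rmse,
        cv_se=best_se,
        null_rmse=None,
        seed=seed,
        stage=stage,
        fitted=fitted,
        bounds=bounds,
    )


def null_model_check(
    frame: ClusterFrame,
    final: InterpModel,
    learner_pool: tuple = DEFAULT_POOL,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, bool]:
    """CV RMSE of the best learner refitted on ALL covariates; the final
    model passes when its RMSE does not exceed it."""
    best = final.members[0]
    y = frame.table["target"].to_numpy(dtype=float)
    oof, fold_rmse, _ = _cv_predictions(
        frame, best, frame.covariate_names, k_folds, seed
    )
    null_rmse, _ = _rmse_se(y, oof, fold_rmse)
    final.null_rmse = null_rmse
    return null_rmse, final.cv_rmse <= null_rmse


def predict_grid(
    model: InterpModel, covariates: RasterStack, bounds: tuple | None = None
) -> PredictedLayer:
    """Cellwise prediction over the stack, clipped to bounds, nodata kept."""
    missing = [c for c in model.covariates if c not in covariates]
    if missing:
        raise ValueError(f"missing covariate bands: {missing}")
    bounds = bounds if bounds is not None else model.bounds
    nrow, ncol = covariates.shape
    arr = covariates.as_array(model.covariates) if model.covariates else None
    nodata = np.zeros((nrow, ncol), dtype=bool)
    if arr is not None:
        nodata |= np.isnan(arr).any(axis=0)

    preds = []
    for learner_id, est in model.fitted.items():
        if learner_id == "knn_coords":
            xs, ys = RasterGrid(np.zeros((nrow, ncol)), covariates.transform).cell_centers()
            X = np.column_stack([xs.ravel(), ys.ravel()])
        elif arr is None:
            X = np.zeros((nrow * ncol, 1))
        else:
            X = arr.reshape(len(model.covariates), -1).T
        Xf = np.where(np.isnan(X), 0.0, X)
        preds.append(est.predict(Xf))
    mean_pred = np.mean(preds, axis=0).reshape(nrow, ncol)

    lo, hi = bounds
    n_clipped = int(((mean_pred < lo) | (mean_pred > hi))[~nodata].sum())
    if n_clipped:
        log.info("target %s: clipped %d cells to %s", model.target, n_clipped, bounds)
    out = np.clip(mean_pred, lo, hi)
    out[nodata] = np.nan
    grid = RasterGrid(out, covariates.transform, name=model.target)
    return PredictedLayer(grid=grid, target=model.target, bounds=bounds,
                          n_clipped=n_clipped)


def two_stage_interpolate(
    survey: pd.DataFrame,
    weights: np.ndarray,
    stage1_targets: list,
    stage2_targets: list,
    covariates: RasterStack,
    learner_pool: tuple = DEFAULT_POOL,
    k_folds: int = 5,
    seed: int = 0,
    stage2_values: dict | None = None,
) -> tuple[dict, dict]:
    """Interpolate stage-1 targets from base covariates, then stage-2
    targets from base covariates plus the stage-1 predicted layers.

    ``stage2_values`` may map target names to per-respondent numeric
    arrays (e.g. index scores) that are not survey columns.
    Returns ``(layers, models)`` keyed by target name.
    """
    names1 = {t.name for t in stage1_targets}
    names2 = {t.name for t in stage2_targets}
    overlap = names1 & names2
    if overlap:
        raise ValueError(f"targets in both stages (circular dependency): {sorted(overlap)}")

    layers: dict[str, PredictedLayer] = {}
    models: dict[str, InterpModel] = {}
    for spec in stage1_targets:
        frame = build_cluster_frame(survey, weights, spec, covariates)
        model = select_model(frame, learner_pool, k_folds, seed,
                             bounds=spec.bounds, stage=1)
        null_model_check(frame, model, learner_pool, k_folds, seed)
        layer = predict_grid(model, covariates)
        layers[spec.name] = layer
        models[spec.name] = model

    stack2 = RasterStack(dict(covariates.layers), covariates.transform)
    for name, layer in layers.items():
        stack2.add(f"s1_{name}", layer.grid.data)

    for spec in stage2_targets:
        vals = (stage2_values or {}).get(spec.name)
        frame = build_cluster_frame(survey, weights, spec, stack2, values=vals)
        model = select_model(frame, learner_pool, k_folds, seed,
                             bounds=spec.bounds, stage=2)
        null_model_check(frame, model, learner_pool, k_folds, seed)
        layers[spec.name] = predict_grid(model, stack2)
        models[spec.name] = model
    return layers, models


def renormalize_terciles(
    low: PredictedLayer, mid: PredictedLayer, high: PredictedLayer
) -> tuple[PredictedLayer, PredictedLayer, PredictedLayer]:
    """Clip the three share layers to [0, 1] and scale each cell to sum to 1.

    Cells where all three shares are zero become equal thirds (flagged in
    the log)."""
    arrs = [np.clip(l.grid.data, 0.0, 1.0) for l in (low, mid, high)]
    total = arrs[0] + arrs[1] + arrs[2]
    zero = (total == 0) & ~np.isnan(total)
    if zero.any():
        log.warning("%d cells had all-zero tercile shares; set to equal thirds",
                    int(zero.sum()))
    out = []
    for arr, src in zip(arrs, (low, mid, high)):
        normed = np.where(zero, 1.0 / 3.0, arr / np.where(total == 0, 1.0, total))
        normed[np.isnan(total)] = np.nan
        out.append(
            PredictedLayer(
                grid=src.grid.copy_with(normed), target=src.target, bounds=(0.0, 1.0)
            )
        )
    return tuple(out)
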