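"""Categorical index construction via Multiple Correspondence Analysis.

Each determinant index is the first dimension of a weighted MCA on the
complete disjunctive (indicator) coding of its categorical inputs. The
fitted model stores everything needed to score new respondents
reproducibly: category coordinates, the sign that aligns the index with
its anchor input, min/max normalization bounds, and weighted tercile
cutpoints. The convenience determinant is a composite: the sum of the
accessibility and the time/financial-burden sub-indices, renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndexSpec",
    "McaModel",
    "IndexScores",
    "fit_mca",
    "bin_continuous",
    "score_index",
    "composite_convenience",
    "driver_correlations",
    "mca_diagnostics",
]

TERCILE_LABELS = ("low", "mid", "high")


@dataclass(frozen=True)
class IndexSpec:
    """Definition of one determinant index.

    ``anchor`` is an ``(input, direction)`` pair: after fitting, the sign
    of the index is flipped if needed so that the weighted correlation
    between the anchor input (rank-coded) and the index has the stated
    direction (+1 or -1).
    """

    name: str
    inputs: tuple
    anchor: tuple  # (input_name, +1 | -1)
    continuous_inputs: dict = field(default_factory=dict)  # name -> n_bins

    def __post_init__(self) -> None:
        if len(self.inputs) < 2:
            raise ValueError(f"index {self.name!r} needs >= 2 inputs")
        if self.anchor[0] not in self.inputs:
            raise ValueError(f"anchor {self.anchor[0]!r} not among inputs")
        if self.anchor[1] not in (-1, 1):
            raise ValueError("anchor direction must be +1 or -1")


@dataclass
class McaModel:
    name: str
    inputs: tuple
    category_coords: dict  # (input, category) -> dim-1 principal coordinate
    eigenvalues: np.ndarray
    inertia_share_raw: float
    inertia_share_corrected: float
    sign: int
    norm_min: float
    norm_max: float
    tercile_cutpoints: tuple
    n_levels: tuple = ()  # categories per input, fit order


@dataclass
class IndexScores:
    name: str
    score_raw: np.ndarray
    score_0_100: np.ndarray
    tercile: np.ndarray  # object array of "low"/"mid"/"high"
    index: pd.Index = None  # respondent index the scores align to


def _as_categorical_codes(col: pd.Series) -> tuple[np.ndarray, list]:
    cats = sorted(col.dropna().unique(), key=str)
    codes = col.map({c: i for i, c in enumerate(cats)}).to_numpy(dtype=float)
    return codes, cats


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Weighted quantiles by cumulative-mass inversion (left-continuous)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    return np.interp(np.atleast_1d(q), cum, v)


def bin_continuous(
    values, weights=None, n_bins: int = 3, prefix: str = "q"
) -> pd.Series:
    """Transform a continuous column into ordered weighted-quantile bins.

    Ties are resolved to the lower bin. If there are fewer distinct
    values than bins, the bin count is reduced with a warning.
    """
    values = pd.Series(values)
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("bin_continuous requires finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    w = np.ones_like(arr) if weights is None else np.asarray(weights, dtype=float)

    n_distinct = len(np.unique(arr))
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct values; reducing bins from {n_bins}",
            stacklevel=2,
        )
        n_bins = max(1, n_distinct)
    if n_bins == 1:
        return pd.Series([f"{prefix}1"] * len(arr), index=values.index)

    qs = np.arange(1, n_bins) / n_bins
    cuts = weighted_quantile(arr, w, qs)
    cuts = np.unique(cuts)
    # value <= cut -> lower bin (ties to lower)
    codes = np.searchsorted(cuts, arr, side="left")
    codes = np.minimum(codes, len(cuts))
    labels = [f"{prefix}{i + 1}" for i in range(len(cuts) + 1)]
    return pd.Series([labels[c] for c in codes], index=values.index)


def _indicator_matrix(
    survey: pd.DataFrame, inputs: tuple
) -> tuple[np.ndarray, list, np.ndarray]:
    blocks, cat_keys, keep = [], [], np.ones(len(survey), dtype=bool)
    for name in inputs:
        keep &= survey[name].notna().to_numpy()
    sub = survey.loc[keep]
    if len(sub) < 2:
        raise ValueError("fewer than 2 complete respondents for MCA")
    for name in inputs:
        col = sub[name]
        cats = sorted(col.unique(), key=str)
        if len(cats) < 2:
            raise ValueError(f"input {name!r} is constant; cannot enter MCA")
        ind = np.zeros((len(sub), len(cats)))
        for j, c in enumerate(cats):
            ind[:, j] = (col == c).to_numpy()
        blocks.append(ind)
        cat_keys.extend((name, c) for c in cats)
    return np.hstack(blocks), cat_keys, keep


def _benzecri_share(eigenvalues: np.ndarray, n_vars: int) -> tuple[float, float]:
    lam = np.asarray(eigenvalues, dtype=float)
    raw = float(lam[0] / lam.sum()) if lam.sum() > 0 else 0.0
    q = n_vars
    above = lam[lam > 1.0 / q]
    if above.size == 0:
        return raw, 0.0
    corr = ((q / (q - 1.0)) * (above - 1.0 / q)) ** 2
    return raw, float(corr[0] / corr.sum())


def _rank_codes(col: pd.Series) -> np.ndarray:
    codes, _ = _as_categorical_codes(col)
    return codes


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def fit_mca(
    survey: pd.DataFrame, spec: IndexSpec, weights: np.ndarray | None = None
) -> McaModel:
    """Fit a weighted MCA on the indicator matrix of the spec's inputs.

    Respondents missing any input are dropped from the fit (listwise per
    index). Dimension-1 category principal coordinates, raw and
    Benzecri-corrected inertia shares, anchor-aligned sign, weighted
    min/max normalization bounds and weighted tercile cutpoints are all
    stored on the returned model.
    """
    if len(survey) < 2:
        raise ValueError("single-respondent survey cannot support MCA")
    z, cat_keys, keep = _indicator_matrix(survey, spec.inputs)
    sub = survey.loc[keep]
    w = np.ones(len(survey)) if weights is None else np.asarray(weights, dtype=float)
    w = w[keep]

    n, total_cats = z.shape
    q = len(spec.inputs)
    grand = w.sum() * q
    p = (w[:, None] * z) / grand
    r = w / w.sum()  # row masses
    c = p.sum(axis=0)  # column masses
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    eigenvalues = sv**2
    # dim 1 is the leading non-trivial axis (indicator CA has no trivial axis
    # left after centering)
    g1 = vt[0] * sv[0] / np.sqrt(c)  # category principal coordinates, dim 1

    raw_share, corr_share = _benzecri_share(eigenvalues, q)

    coords = {key: float(g1[j]) for j, key in enumerate(cat_keys)}
    raw_scores = z @ g1 / q

    anchor_name, direction = spec.anchor
    anchor_codes = _rank_codes(sub[anchor_name])
    r_anchor = _weighted_corr(anchor_codes, raw_scores, w)
    sign = 1
    if np.isfinite(r_anchor) and r_anchor * direction < 0:
        sign = -1
    signed = sign * raw_scores

    norm_min, norm_max = float(signed.min()), float(signed.max())
    if norm_max <= norm_min:
        raise ValueError(f"index {spec.name!r} is degenerate (constant scores)")
    scaled = 100.0 * (signed - norm_min) / (norm_max - norm_min)
    cutpoints = tuple(weighted_quantile(scaled, w, [1 / 3, 2 / 3]))

    return McaModel(
        name=spec.name,
        inputs=spec.inputs,
        category_coords=coords,
        eigenvalues=eigenvalues,
        inertia_share_raw=raw_share,
        inertia_share_corrected=corr_share,
        sign=sign,
        norm_min=norm_min,
        norm_max=norm_max,
        tercile_cutpoints=cutpoints,
        n_levels=tuple(
            len({k for k in coords if k[0] == name}) for name in spec.inputs
        ),
    )


def _classify_terciles(scores: np.ndarray, cutpoints: tuple) -> np.ndarray:
    lo, hi = cutpoints
    if not hi > lo:
        warnings.warn("degenerate tercile cutpoints; collapsing levels", stacklevel=2)
    out = np.full(scores.shape, "low", dtype=object)
    out[scores > lo] = "mid"  # strictly greater than cutpoint enters upper class
    out[scores > hi] = "high"
    return out


def score_index(
    survey: pd.DataFrame, model: McaModel, clip: bool = True
) -> IndexScores:
    """Score respondents with a fitted model.

    Raw score is the mean of the dimension-1 category coordinates of the
    respondent's responses (the standard MCA row coordinate up to a
    constant). Unseen categories raise; out-of-range scores on new data
    are clipped to the model bounds with a warning.
    """
    keep = np.ones(len(survey), dtype=bool)
    for name in model.inputs:
        keep &= survey[name].notna().to_numpy()
    sub = survey.loc[keep]
    q = len(model.inputs)
    raw = np.zeros(len(sub))
    for name in model.inputs:
        col = sub[name]
        mapping = {c: v for (inp, c), v in model.category_coords.items() if inp == name}
        unseen = set(col.unique()) - set(mapping)
        if unseen:
            raise ValueError(f"unseen categories for input {name!r}: {sorted(map(str, unseen))}")
        raw += col.map(mapping).to_numpy(dtype=float)
    raw = model.sign * raw / q

    scaled = 100.0 * (raw - model.norm_min) / (model.norm_max - model.norm_min)
    # float-epsilon overshoot at the fitted extremes is not "new data out
    # of range"; only warn beyond a real tolerance
    n_out = int(((scaled < -1e-6) | (scaled > 100 + 1e-6)).sum())
    if n_out and clip:
        warnings.warn(
            f"{n_out} scores outside fitted bounds clipped to [0, 100]",
            stacklevel=2,
        )
    if clip:
        scaled = np.clip(scaled, 0.0, 100.0)
    terciles = _classify_terciles(scaled, model.tercile_cutpoints)
    return IndexScores(
        name=model.name,
        score_raw=raw,
        score_0_100=scaled,
        tercile=terciles,
        index=sub.index,
    )


def composite_convenience(
    accessibility: IndexScores,
    time_financial: IndexScores,
    weights: np.ndarray | None = None,
    name: str = "convenience",
) -> IndexScores:
    """Sum the two convenience sub-indices and renormalize to 0-100."""
    if not accessibility.index.equals(time_financial.index):
        raise ValueError("sub-indices cover different respondent sets")
    w = (
        np.ones(len(accessibility.index))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    raw = accessibility.score_0_100 + time_financial.score_0_100
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        warnings.warn("composite index is constant; terciles degenerate", stacklevel=2)
        scaled = np.zeros_like(raw)
        cutpoints = (0.0, 0.0)
    else:
        scaled = 100.0 * (raw - lo) / (hi - lo)
        cutpoints = tuple(weighted_quantile(scaled, w, [1 / 3, 2 / 3]))
    return IndexScores(
        name=name,
        score_raw=raw,
        score_0_100=scaled,
        tercile=_classify_terciles(scaled, cutpoints),
        index=accessibility.index,
    )


def driver_correlations(
    survey: pd.DataFrame,
    index: IndexScores,
    spec: IndexSpec,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted Pearson correlation of each (rank-coded) input with the index,
    with a 95% significance flag from the t approximation."""
    sub = survey.loc[index.index]
    w = np.ones(len(sub)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    n = len(sub)
    for name in spec.inputs:
        codes = _rank_codes(sub[name])
        r = _weighted_corr(codes, index.score_0_100, w)
        if np.isnan(r):
            rows.append({"input": name, "r": np.nan, "significant_at_95": False})
            continue
        r_c = min(max(r, -0.9999999), 0.9999999)
        t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
        rows.append({"input": name, "r": r, "significant_at_95": bool(p < 0.05)})
    out = pd.DataFrame(rows)
    out["abs_r"] = out["r"].abs()
    return out.sort_values("abs_r", ascending=False).drop(columns="abs_r").reset_index(
        drop=True
    )


def mca_diagnostics(model: McaModel, threshold: float = 0.74) -> dict:
    """Raw and corrected dimension-1 explained-variance shares with a flag
    when the corrected share falls below ``threshold``."""
    return {
        "index": model.name,
        "inertia_share_raw": model.inertia_share_raw,
        "inertia_share_corrected": model.inertia_share_corrected,
        "threshold": threshold,
        "below_threshold": model.inertia_share_corrected < threshold,
    }
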