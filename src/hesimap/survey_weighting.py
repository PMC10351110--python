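"""Post-stratification reweighting by iterative proportional fitting (raking).

Weights are adjusted multiplicatively, one margin at a time, until every
weighted categorical margin matches its reference target distribution.
Final weights are normalized to sum to the survey n so downstream index
normalization is weight-scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarginSpec", "WeightResult", "ipf_rake", "weighted_share"]


@dataclass(frozen=True)
class MarginSpec:
    """Reference marginal distribution for one categorical variable."""

    variable: str
    targets: dict = field(default_factory=dict)  # category -> population proportion

    def __post_init__(self) -> None:
        props = np.array(list(self.targets.values()), dtype=float)
        if (props < 0).any():
            raise ValueError(f"margin {self.variable}: negative target proportion")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"margin {self.variable}: targets sum to {props.sum()}, expected 1"
            )


@dataclass
class WeightResult:
    weights: np.ndarray
    iterations: int
    max_margin_error: float
    converged: bool


def _margin_error(survey: pd.DataFrame, weights: np.ndarray, margins) -> float:
    worst = 0.0
    total = weights.sum()
    for m in margins:
        shares = (
            pd.Series(weights, index=survey.index)
            .groupby(survey[m.variable], observed=False)
            .sum()
            / total
        )
        for cat, target in m.targets.items():
            worst = max(worst, abs(shares.get(cat, 0.0) - target))
    return worst


def ipf_rake(
    survey: pd.DataFrame,
    margins: list[MarginSpec],
    tol: float = 1e-6,
    max_iter: int = 100,
    base_weights: np.ndarray | None = None,
    weight_cap: float | None = None,
) -> WeightResult:
    """Rake survey weights to match reference margins.

    One iteration is a full sweep over the margins in listed order. A
    survey category with zero respondents but a positive target is a
    structural zero and raises. Non-convergence within ``max_iter`` is
    returned with ``converged=False``, never silently.
    """
    n = len(survey)
    if n == 0:
        raise ValueError("empty survey")
    for m in margins:
        if m.variable not in survey.columns:
            raise ValueError(f"margin variable {m.variable!r} not in survey")
        col = survey[m.variable]
        if col.isna().any():
            raise ValueError(f"margin variable {m.variable!r} has missing values")
        present = set(col.unique())
        for cat, target in m.targets.items():
            if target > 0 and cat not in present:
                raise ValueError(
                    f"structural zero: category {cat!r} of {m.variable!r} has a "
                    f"positive target ({target}) but no respondents"
                )

    w = (
        np.ones(n, dtype=float)
        if base_weights is None
        else np.asarray(base_weights, dtype=float).copy()
    )
    if (w <= 0).any():
        raise ValueError("base weights must be positive")

    iterations = 0
    converged = _margin_error(survey, w, margins) <= tol
    while not converged and iterations < max_iter:
        iterations += 1
        for m in margins:
            col = survey[m.variable]
            current = pd.Series(w, index=survey.index).groupby(col, observed=False).sum()
            total = w.sum()
            factors = {
                cat: (t * total / current[cat]) if current.get(cat, 0) > 0 else 1.0
                for cat, t in m.targets.items()
            }
            w *= col.map(factors).fillna(1.0).to_numpy(dtype=float)
        if weight_cap is not None:
            mean_w = w.mean()
            w = np.minimum(w, weight_cap * mean_w)
        converged = _margin_error(survey, w, margins) <= tol
    if iterations == 0:
        iterations = 1  # the fixed-point check itself counts as a pass

    w *= n / w.sum()
    return WeightResult(
        weights=w,
        iterations=iterations,
        max_margin_error=_margin_error(survey, w, margins),
        converged=converged,
    )


def weighted_share(
    survey: pd.DataFrame, variable: str, weights: np.ndarray
) -> dict:
    """Weighted category proportions of one categorical column."""
    if len(survey) == 0:
        raise ValueError("empty survey")
    w = pd.Series(np.asarray(weights, dtype=float), index=survey.index)
    shares = w.groupby(survey[variable], observed=True).sum() / w.sum()
    return shares.to_dict()
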