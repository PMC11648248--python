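"""Entropy-weighted TOPSIS comprehensive benefit scoring.

The decision matrix has planting methods (or individual records) as
alternatives and the five benefit indicators as criteria; GHG emissions is a
cost criterion, the rest are benefit criteria.  Criterion weights come from
the entropy method: each column is min-max normalized (cost columns inverted
as ``max - x`` first), rescaled to a proportion vector, and weighted by one
minus its Shannon entropy (scaled by ``1/ln m``), so criteria that
discriminate more between alternatives weigh more.  TOPSIS then ranks
alternatives by relative closeness to the ideal point under vector (root
sum-of-squares) column normalization; the comprehensive score is closeness
times 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BENEFIT_COLUMNS

#: default direction flags: True = cost criterion (smaller is better)
DEFAULT_COST_FLAGS = {"yield": False, "ghg": True, "eb": False, "pfp": False, "eue": False}


class ScoringError(ValueError):
    pass


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values with per-criterion direction flags."""

    values: pd.DataFrame
    cost_flags: dict[str, bool]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ScoringError("decision matrix contains missing cells")
        if len(self.values) < 2:
            raise ScoringError("need at least 2 alternatives")
        missing = set(self.values.columns) - set(self.cost_flags)
        if missing:
            raise ScoringError(f"direction flags missing for criteria: {sorted(missing)}")

    @property
    def cost_mask(self) -> np.ndarray:
        return np.array([self.cost_flags[c] for c in self.values.columns])


@dataclass
class ScoreResult:
    """Entropy weights, TOPSIS distances, scores and ranks."""

    weights: pd.Series
    d_ideal: pd.Series
    d_anti: pd.Series
    closeness: pd.Series
    mode: str = "method-means"
    scores: pd.Series = field(init=False)
    ranks: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.scores = (100.0 * self.closeness).rename("score")
        # deterministic tie-break: equal scores ordered by alternative label
        order = sorted(self.scores.index, key=lambda a: (-self.scores[a], str(a)))
        self.ranks = pd.Series(
            {a: i + 1 for i, a in enumerate(order)}, name="rank"
        ).reindex(self.scores.index)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "rank": self.ranks,
             "d_ideal": self.d_ideal, "d_anti": self.d_anti}
        ).sort_values("rank")


def entropy_weights(matrix: DecisionMatrix) -> pd.Series:
    """Entropy-method criterion weights (sum to 1)."""
    X = matrix.values.to_numpy(dtype=float).copy()
    cost = matrix.cost_mask
    X[:, cost] = X[:, cost].max(axis=0) - X[:, cost]
    rng = X.max(axis=0) - X.min(axis=0)
    constant = rng == 0
    denom = np.where(constant, 1.0, rng)
    X = (X - X.min(axis=0)) / denom
    m = X.shape[0]
    colsum = X.sum(axis=0)
    P = X / np.where(colsum == 0, 1.0, colsum)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    E = -plogp.sum(axis=0) / np.log(m)
    E = np.where(constant, 1.0, E)
    raw = 1.0 - E
    if np.all(raw <= 0):
        warnings.warn("all criteria constant; falling back to uniform weights")
        raw = np.ones_like(raw)
    w = raw / raw.sum()
    return pd.Series(w, index=matrix.values.columns, name="weight")


def topsis(matrix: DecisionMatrix, weights: pd.Series | np.ndarray) -> ScoreResult:
    """TOPSIS relative closeness under vector column normalization."""
    X = matrix.values.to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    norms = np.sqrt((X ** 2).sum(axis=0))
    zero = norms == 0
    if zero.any():
        bad = matrix.values.columns[zero][0]
        raise ScoringError(f"zero-norm criterion column {bad!r}")
    V = X / norms * w
    cost = matrix.cost_mask
    ideal = np.where(cost, V.min(axis=0), V.max(axis=0))
    anti = np.where(cost, V.max(axis=0), V.min(axis=0))
    d_plus = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    with np.errstate(invalid="ignore"):
        closeness = np.where(denom == 0, 0.5, d_minus / np.where(denom == 0, 1, denom))
    idx = matrix.values.index
    return ScoreResult(
        weights=pd.Series(w, index=matrix.values.columns, name="weight"),
        d_ideal=pd.Series(d_plus, index=idx, name="d_ideal"),
        d_anti=pd.Series(d_minus, index=idx, name="d_anti"),
        closeness=pd.Series(closeness, index=idx, name="closeness"),
    )


def score_methods(
    benefit_df: pd.DataFrame,
    mode: str = "method-means",
    cost_flags: dict[str, bool] | None = None,
) -> ScoreResult:
    """Comprehensive benefit score per planting method.

    ``method-means`` builds the methods x indicators matrix of per-method mean
    benefits and scores those four alternatives; ``record-level`` scores every
    record and averages closeness per method.
    """
    cost_flags = dict(DEFAULT_COST_FLAGS if cost_flags is None else cost_flags)
    cols = list(BENEFIT_COLUMNS)
    if mode == "method-means":
        means = benefit_df.groupby("method", sort=False)[cols].mean()
        matrix = DecisionMatrix(means, cost_flags)
        res = topsis(matrix, entropy_weights(matrix))
        res.mode = mode
        return res
    if mode == "record-level":
        values = benefit_df[cols].dropna()
        matrix = DecisionMatrix(values, cost_flags)
        res = topsis(matrix, entropy_weights(matrix))
        per_method = res.closeness.groupby(
            benefit_df.loc[values.index, "method"]
        ).mean()
        out = ScoreResult(
            weights=res.weights,
            d_ideal=res.d_ideal.groupby(benefit_df.loc[values.index, "method"]).mean(),
            d_anti=res.d_anti.groupby(benefit_df.loc[values.index, "method"]).mean(),
            closeness=per_method,
            mode=mode,
        )
        return out
    raise ScoringError(f"unknown scoring mode {mode!r}")
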