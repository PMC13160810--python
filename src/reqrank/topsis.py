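"""TOPSIS: rank alternatives by relative closeness to the ideal solution.

Given mean Likert scores ``f_ij`` (alternatives × indicators) and indicator
weights ``W_j``:

1. vector-normalize columns, ``R_ij = f_ij / √(Σ_i f_ij²)``;
2. weight, ``u_ij = W_j · R_ij``;
3. positive/negative ideals ``M_j± = max/min_i u_ij`` (reversed for cost
   indicators);
4. Euclidean distances ``S_i± = √(Σ_j (u_ij − M_j±)²)``;
5. relative closeness ``C_i = S_i− / (S_i+ + S_i−)``, ranked descending.

``C_i`` lies in [0, 1], is invariant to positive rescaling of the weight
vector, and for any two-alternative all-benefit problem satisfies
``C_1 + C_2 = 1``.  Identical alternatives (``S_i+ + S_i− = 0``) get
``C_i = 0.5`` by convention and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, NumericError, ShapeError
from .survey_io import ScoreTable

DIRECTIONS = ("benefit", "cost")


@dataclass(frozen=True)
class EvaluationMatrix:
    """Mean Likert scores per alternative × indicator (1–7 points)."""

    alternatives: tuple[str, ...]
    indicators: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.alternatives), len(self.indicators)):
            raise ShapeError(
                f"matrix shape {v.shape} does not match "
                f"{len(self.alternatives)}×{len(self.indicators)} labels"
            )
        if np.isnan(v).any():
            raise CompletenessError("evaluation matrix has missing cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alternatives, columns=self.indicators)


@dataclass(frozen=True)
class TopsisResult:
    alternatives: tuple[str, ...]
    indicators: tuple[str, ...]
    normalized: np.ndarray
    weighted: np.ndarray
    ideal_positive: np.ndarray
    ideal_negative: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray
    closeness: np.ndarray
    ranking: tuple[str, ...]
    degenerate: tuple[str, ...] = ()  # alternatives with S+ + S− = 0

    def closeness_by_alternative(self) -> dict[str, float]:
        return dict(zip(self.alternatives, map(float, self.closeness)))


def aggregate_scores(scores: ScoreTable) -> EvaluationMatrix:
    """Pool all raters (expert and user groups alike) into mean scores.

    Every alternative × indicator cell needs at least one score; means are
    kept at full precision internally.
    """
    if not scores.records:
        raise CompletenessError("empty score table")
    df = scores.to_frame()
    alternatives = tuple(dict.fromkeys(df["alternative_id"]))
    indicators = tuple(dict.fromkeys(df["indicator_id"]))
    means = df.groupby(["alternative_id", "indicator_id"], sort=False)["score"].mean()
    values = np.empty((len(alternatives), len(indicators)))
    for i, alt in enumerate(alternatives):
        for j, ind in enumerate(indicators):
            if (alt, ind) not in means.index:
                raise CompletenessError(f"no scores for cell ({alt!r}, {ind!r})")
            values[i, j] = means[(alt, ind)]
    return EvaluationMatrix(alternatives=alternatives, indicators=indicators, values=values)


def vector_normalize(matrix: EvaluationMatrix) -> np.ndarray:
    """Columnwise vector normalization; every column gets unit Euclidean norm."""
    norms = np.sqrt((matrix.values**2).sum(axis=0))
    if np.any(norms == 0):
        bad = [matrix.indicators[j] for j in np.flatnonzero(norms == 0)]
        raise NumericError(f"all-zero column(s) {bad} cannot be normalized")
    return matrix.values / norms


def apply_weights(normalized: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] != normalized.shape[1]:
        raise ShapeError(
            f"weight count {w.shape} does not match {normalized.shape[1]} indicators"
        )
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return normalized * w


def ideal_solutions(
    weighted: np.ndarray, directions: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative ideal rows (max/min per benefit column, reversed for cost)."""
    if len(directions) != weighted.shape[1]:
        raise ShapeError("one direction label per indicator required")
    a_pos = np.empty(weighted.shape[1])
    a_neg = np.empty(weighted.shape[1])
    for j, direction in enumerate(directions):
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        col = weighted[:, j]
        if direction == "benefit":
            a_pos[j], a_neg[j] = col.max(), col.min()
        else:
            a_pos[j], a_neg[j] = col.min(), col.max()
    return a_pos, a_neg


def closeness(
    weighted: np.ndarray,
    a_pos: np.ndarray,
    a_neg: np.ndarray,
    *,
    alternatives: tuple[str, ...],
    indicators: tuple[str, ...],
    normalized: np.ndarray | None = None,
) -> TopsisResult:
    """Euclidean distances to both ideals and relative closeness, ranked."""
    s_plus = np.sqrt(((weighted - a_pos) ** 2).sum(axis=1))
    s_minus = np.sqrt(((weighted - a_neg) ** 2).sum(axis=1))
    total = s_plus + s_minus
    degenerate = tuple(alternatives[i] for i in np.flatnonzero(total == 0))
    c = np.where(total > 0, s_minus / np.where(total > 0, total, 1.0), 0.5)
    order = sorted(range(len(alternatives)), key=lambda i: (-c[i], i))
    return TopsisResult(
        alternatives=alternatives,
        indicators=indicators,
        normalized=normalized if normalized is not None else weighted,
        weighted=weighted,
        ideal_positive=a_pos,
        ideal_negative=a_neg,
        s_plus=s_plus,
        s_minus=s_minus,
        closeness=c,
        ranking=tuple(alternatives[i] for i in order),
        degenerate=degenerate,
    )


def evaluate(
    matrix: EvaluationMatrix,
    weights: Sequence[float] | Mapping[str, float],
    directions: Sequence[str] | Mapping[str, str] | None = None,
) -> TopsisResult:
    """Run the full normalize → weight → ideals → closeness chain."""
    if isinstance(weights, Mapping):
        missing = [i for i in matrix.indicators if i not in weights]
        if missing:
            raise CompletenessError(f"no weight for indicator(s) {missing}")
        weights = [weights[i] for i in matrix.indicators]
    if directions is None:
        directions = ["benefit"] * len(matrix.indicators)
    elif isinstance(directions, Mapping):
        directions = [directions.get(i, "benefit") for i in matrix.indicators]
    normalized = vector_normalize(matrix)
    weighted = apply_weights(normalized, weights)
    a_pos, a_neg = ideal_solutions(weighted, directions)
    return closeness(
        weighted,
        a_pos,
        a_neg,
        alternatives=matrix.alternatives,
        indicators=matrix.indicators,
        normalized=normalized,
    )


def rank_report(result: TopsisResult, precision: int = 3) -> pd.DataFrame:
    """Ranked table of (alternative, S+, S−, C_i, rank); ties keep input order."""
    rank_of = {alt: k + 1 for k, alt in enumerate(result.ranking)}
    c = result.closeness
    tied = {
        result.alternatives[i]
        for i in range(len(c))
        for j in range(len(c))
        if i != j and c[i] == c[j]
    }
    rows = [
        {
            "alternative": alt,
            "s_plus": round(float(result.s_plus[i]), precision),
            "s_minus": round(float(result.s_minus[i]), precision),
            "closeness": round(float(c[i]), precision),
            "rank": rank_of[alt],
            "tie": alt in tied,
        }
        for i, alt in enumerate(result.alternatives)
    ]
    return pd.DataFrame(rows)
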