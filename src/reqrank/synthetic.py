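"""Synthetic questionnaire data with planted ground truth.

Every analysis stage gets a parameter-recovery oracle:

* Kano responses — each respondent answers from the cells of the
  evaluation table that map to the indicator's planted category, with
  probability ε replaced by a uniform draw over all 25 cells.  At ε = 0 the
  planted category is recovered exactly.
* Pairwise matrices — ``a_ij = (w_i/w_j)·exp(e_ij)`` with antisymmetric
  zero-mean normal log-noise, so positivity and reciprocity hold by
  construction; optional snapping to the Saaty value set.
* Likert scores — true mean plus Gaussian noise, rounded and clipped to the
  1–7 scale.
* Factor-structured items — one common factor with loading λ, giving a
  population inter-item correlation of λ² (Spearman–Brown closed forms for
  α follow).

All generators are pure functions of (specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kano as _kano
from .ahp import PairwiseMatrix
from .survey_io import (
    ANSWER_LEVELS,
    Indicator,
    ResponseRecord,
    ResponseTable,
    ScoreRecord,
    ScoreTable,
)

#: Saaty judgment values used when snapping generated matrices.
SAATY_VALUES = np.array(
    [1 / 9, 1 / 8, 1 / 7, 1 / 6, 1 / 5, 1 / 4, 1 / 3, 1 / 2, 1, 2, 3, 4, 5, 6, 7, 8, 9]
)

PLANTABLE = ("A", "O", "M", "I", "R")


@dataclass(frozen=True)
class KanoPlantSpec:
    """Planted per-indicator categories plus a uniform answer-error rate."""

    categories: Mapping[str, str]  # indicator id -> planted category
    error_rate: float = 0.0
    n_respondents: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")
        for ind, cat in self.categories.items():
            if cat == "Q":
                raise ValueError(
                    f"{ind}: category Q is not plantable (it denotes contradiction)"
                )
            if cat not in PLANTABLE:
                raise ValueError(f"{ind}: unknown category {cat!r}")


@dataclass(frozen=True)
class MatrixPlantSpec:
    """True weight vector and log-normal perturbation scale for one matrix."""

    true_weights: tuple[float, ...]
    sigma: float = 0.0
    snap_to_saaty: bool = False
    seed: int = 0
    items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("true weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("true weights must sum to 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.items and len(self.items) != len(self.true_weights):
            raise ValueError("item labels must match weight count")


def _cells_by_category(table=None) -> dict[str, list[tuple[str, str]]]:
    table = table if table is not None else _kano.load_evaluation_table()
    cells: dict[str, list[tuple[str, str]]] = {}
    for pair, cat in table.items():
        cells.setdefault(cat, []).append(pair)
    for cat in cells:
        cells[cat] = sorted(cells[cat])
    return cells


def generate_kano_responses(
    plant: KanoPlantSpec, indicators: Sequence[Indicator | str] | None = None
) -> ResponseTable:
    """Draw a full response table from planted categories.

    With probability 1−ε the (functional, dysfunctional) pair is uniform
    over the evaluation-table cells of the planted category; with
    probability ε uniform over all 25 cells.
    """
    rng = np.random.default_rng(plant.seed)
    cells = _cells_by_category()
    all_cells = sorted((f, d) for f in ANSWER_LEVELS for d in ANSWER_LEVELS)
    ids = (
        [i.id if isinstance(i, Indicator) else str(i) for i in indicators]
        if indicators is not None
        else sorted(plant.categories)
    )
    records = []
    for resp in range(plant.n_respondents):
        role = "older_adult" if resp % 3 < 2 else "caregiver"
        for ind in ids:
            pool = cells[plant.categories[ind]]
            if plant.error_rate > 0 and rng.random() < plant.error_rate:
                f, d = all_cells[rng.integers(len(all_cells))]
            else:
                f, d = pool[rng.integers(len(pool))]
            records.append(
                ResponseRecord(
                    respondent_id=f"r{resp + 1:04d}",
                    role=role,
                    indicator_id=ind,
                    functional=f,
                    dysfunctional=d,
                )
            )
    return ResponseTable(records)


def generate_pairwise_matrix(plant: MatrixPlantSpec) -> PairwiseMatrix:
    """Perturb the consistent matrix ``w_i/w_j`` with antisymmetric log-noise."""
    rng = np.random.default_rng(plant.seed)
    w = np.asarray(plant.true_weights, dtype=float)
    n = w.shape[0]
    values = np.outer(w, 1.0 / w)
    if plant.sigma > 0:
        e = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        e[iu] = rng.normal(0.0, plant.sigma, size=len(iu[0]))
        e -= e.T
        values = values * np.exp(e)
    if plant.snap_to_saaty:
        iu = np.triu_indices(n, k=1)
        upper = values[iu]
        snapped = SAATY_VALUES[
            np.argmin(np.abs(np.log(upper)[:, None] - np.log(SAATY_VALUES)[None, :]), axis=1)
        ]
        values = np.ones((n, n))
        values[iu] = snapped
        values[(iu[1], iu[0])] = 1.0 / snapped
    np.fill_diagonal(values, 1.0)
    items = plant.items or tuple(f"x{i + 1}" for i in range(n))
    return PairwiseMatrix(items=tuple(items), values=values)


def generate_likert_scores(
    quality: pd.DataFrame,
    sd: float = 0.5,
    n_raters_per_group: int = 20,
    seed: int = 0,
) -> ScoreTable:
    """Discretized-Gaussian rater scores around true cell means.

    ``quality`` is alternatives (rows) × indicators (columns) of true means
    in [1, 7].  Each rater's score is the true mean plus N(0, sd²) noise,
    rounded to the nearest integer and clipped to the scale.  Raters split
    evenly into the expert and user groups.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    means = quality.to_numpy(dtype=float)
    if means.min() < 1 or means.max() > 7:
        raise ValueError("true means must lie within the 1-7 scale")
    rng = np.random.default_rng(seed)
    records = []
    for group in ("expert", "user"):
        for k in range(n_raters_per_group):
            rater = f"{group[0]}{k + 1:03d}"
            for i, alt in enumerate(quality.index):
                for j, ind in enumerate(quality.columns):
                    raw = means[i, j] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    score = int(np.clip(np.rint(raw), 1, 7))
                    records.append(
                        ScoreRecord(
                            rater_id=rater,
                            rater_group=group,
                            alternative_id=str(alt),
                            indicator_id=str(ind),
                            score=score,
                        )
                    )
    return ScoreTable(records)


def generate_factor_items(
    n_subjects: int, n_items: int, loading: float, seed: int = 0
) -> np.ndarray:
    """One-factor item responses ``x = λ·f + √(1−λ²)·e``.

    ``f`` is a per-subject standard-normal factor and ``e`` independent
    standard-normal noise, so the population inter-item correlation is λ².
    """
    if not 0.0 <= loading < 1.0:
        raise ValueError("loading must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(n_subjects, 1))
    e = rng.normal(size=(n_subjects, n_items))
    return loading * f + np.sqrt(1.0 - loading**2) * e
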