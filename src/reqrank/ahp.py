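"""Analytic Hierarchy Process: priority weights and consistency diagnostics.

A judgment matrix ``A`` holds Saaty 1–9 ratio judgments ``a_ij ≈ w_i/w_j``.
Local priorities come from the dominant eigenvector (power iteration) or
from normalized row geometric means.  Consistency is measured by
``CI = (λmax − n)/(n − 1)`` and ``CR = CI / RI(n)`` against Saaty's
random-index table; ``CR < 0.1`` is the conventional pass mark.

Published matrices are not always exactly reciprocal; ``repair_upper`` mode
keeps the strict upper triangle and rebuilds the lower triangle from
reciprocals before weighting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, IntegrityError, NumericError, ShapeError


@dataclass(frozen=True)
class PairwiseMatrix:
    """A labeled square matrix of positive ratio judgments.

    A well-formed judgment matrix has unit diagonal and is reciprocal;
    published matrices sometimes violate both, so those conditions are
    checked by :func:`validate_reciprocity` (and strict-mode weighting)
    rather than at construction, and fixed by
    :func:`repair_from_upper_triangle`.
    """

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.items)
        if v.shape != (n, n):
            raise ShapeError(f"matrix shape {v.shape} does not match {n} items")
        if np.any(v <= 0):
            raise ValueError("judgment entries must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class WeightResult:
    """Priority vector of one judgment matrix plus consistency diagnostics."""

    items: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    ri_used: float
    method: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, map(float, self.weights)))


@dataclass(frozen=True)
class Hierarchy:
    """Criterion-layer and indicator-layer weights synthesized globally."""

    criterion_weights: dict[str, float]
    local_weights: dict[str, dict[str, float]]  # category -> indicator -> local w
    global_weights: dict[str, float]  # indicator -> global w (sums to 1)
    ranking: tuple[str, ...]  # indicators by descending global weight


def load_random_index(path: str | Path | None = None) -> dict[int, float]:
    """Load the random-index table (Saaty's classic values by default)."""
    if path is None:
        text = (resources.files("reqrank.data") / "random_index.csv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    rows = list(csv.DictReader(text.splitlines()))
    return {int(r["n"]): float(r["ri"]) for r in rows}


_RI: dict[int, float] | None = None


def _ri_table() -> dict[int, float]:
    global _RI
    if _RI is None:
        _RI = load_random_index()
    return _RI


def validate_reciprocity(
    matrix: PairwiseMatrix, tol: float = 1e-9
) -> list[tuple[str, str]]:
    """Report all label pairs with ``|a_ij · a_ji − 1| > tol``.

    Diagonal entries different from 1 are reported as ``(label, label)``
    pairs.
    """
    v = matrix.values
    bad = []
    for i in range(matrix.n):
        if abs(v[i, i] - 1.0) > tol:
            bad.append((matrix.items[i], matrix.items[i]))
        for j in range(i + 1, matrix.n):
            if abs(v[i, j] * v[j, i] - 1.0) > tol:
                bad.append((matrix.items[i], matrix.items[j]))
    return bad


def repair_from_upper_triangle(matrix: PairwiseMatrix) -> PairwiseMatrix:
    """Rebuild a reciprocal matrix from the strict upper triangle.

    Idempotent; the diagonal is set to 1 and the lower triangle to the
    elementwise reciprocal of the upper.
    """
    v = matrix.values.copy()
    n = matrix.n
    iu = np.triu_indices(n, k=1)
    out = np.ones((n, n))
    out[iu] = v[iu]
    out[(iu[1], iu[0])] = 1.0 / v[iu]
    return PairwiseMatrix(items=matrix.items, values=out)


def consistency(
    lambda_max: float, n: int, ri_table: Mapping[int, float] | None = None
) -> tuple[float, float]:
    """Consistency index and ratio for a matrix of order ``n``.

    ``CI = (λmax − n)/(n − 1)``; ``CR = CI / RI(n)``, defined as 0 for
    ``n ≤ 2`` (a 2×2 reciprocal matrix is always consistent).
    """
    if n < 1:
        raise ValueError("order must be ≥ 1")
    if n == 1:
        return 0.0, 0.0
    if lambda_max < n - 1e-9:
        raise ValueError(f"λmax={lambda_max} below matrix order {n}")
    ci = (lambda_max - n) / (n - 1)
    if n <= 2:
        return ci, 0.0
    table = dict(ri_table) if ri_table is not None else _ri_table()
    if n not in table or table[n] == 0:
        raise ConfigurationError(f"no random-index entry for order n={n}")
    return ci, ci / table[n]


def _power_iteration(v: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000):
    n = v.shape[0]
    w = np.full(n, 1.0 / n)
    for iteration in range(max_iter):
        nxt = v @ w
        nxt = nxt / nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            return nxt, float((v @ nxt / nxt).mean()), iteration + 1
        w = nxt
    raise NumericError(f"power iteration did not converge in {max_iter} iterations")


def priority_weights(
    matrix: PairwiseMatrix,
    method: str = "eigenvector",
    *,
    reciprocity: str = "strict",
    ri_table: Mapping[int, float] | None = None,
) -> WeightResult:
    """Derive the priority vector and consistency diagnostics.

    ``eigenvector``: dominant eigenvector by power iteration (uniform start,
    max-norm tolerance 1e-12), λmax from the mean of ``(A·w)_i / w_i`` at
    convergence.  ``geometric_mean``: normalized row geometric means with the
    same λmax estimate.
    """
    if reciprocity == "repair_upper":
        matrix = repair_from_upper_triangle(matrix)
    elif reciprocity == "strict":
        bad = validate_reciprocity(matrix, tol=1e-9)
        if bad:
            raise IntegrityError(f"matrix is not reciprocal at {bad}; use repair_upper")
    else:
        raise ConfigurationError(f"unknown reciprocity mode {reciprocity!r}")

    v = matrix.values
    n = matrix.n
    if method == "eigenvector":
        w, lam, _ = _power_iteration(v)
    elif method == "geometric_mean":
        gm = np.exp(np.log(v).mean(axis=1))
        w = gm / gm.sum()
        lam = float((v @ w / w).mean())
    else:
        raise ConfigurationError(f"unknown weighting method {method!r}")
    lam = max(lam, float(n))  # guard rounding slightly below n in the consistent limit
    ci, cr = consistency(lam, n, ri_table=ri_table)
    ri = 0.0 if n <= 2 else (dict(ri_table) if ri_table is not None else _ri_table())[n]
    return WeightResult(
        items=matrix.items,
        weights=w,
        lambda_max=lam,
        ci=ci,
        cr=cr,
        ri_used=ri,
        method=method,
    )


def synthesize_global(
    criterion: WeightResult, locals_: Mapping[str, WeightResult]
) -> Hierarchy:
    """Combine criterion-layer and indicator-layer weights multiplicatively.

    ``global_i = w_category(i) · w_local(i)``, renormalized to sum to one
    over all retained indicators; ranking is by descending global weight
    with stable input order on ties.
    """
    seen: set[str] = set()
    crit = criterion.as_dict()
    missing = set(locals_) - set(crit)
    if missing:
        raise IntegrityError(f"local matrices for unknown criteria: {sorted(missing)}")
    global_raw: dict[str, float] = {}
    local_weights: dict[str, dict[str, float]] = {}
    for category in criterion.items:
        if category not in locals_:
            continue
        local = locals_[category]
        local_weights[category] = local.as_dict()
        for ind, lw in local_weights[category].items():
            if ind in seen:
                raise IntegrityError(f"indicator {ind!r} appears in multiple categories")
            seen.add(ind)
            global_raw[ind] = crit[category] * lw
    total = sum(global_raw.values())
    global_weights = {k: v / total for k, v in global_raw.items()}
    order = sorted(
        global_weights, key=lambda k: (-global_weights[k], list(global_weights).index(k))
    )
    return Hierarchy(
        criterion_weights=crit,
        local_weights=local_weights,
        global_weights=global_weights,
        ranking=tuple(order),
    )
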