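"""Questionnaire reliability and validity battery.

Three classical statistics on a subjects × items matrix:

* Cronbach's α — internal consistency,
  ``α = k/(k−1) · (1 − Σ σ²_item / σ²_total)``;
* Kaiser–Meyer–Olkin measure of sampling adequacy, overall and per item,
  comparing zero-order with partial correlations;
* Bartlett's test of sphericity,
  ``χ² = −(n−1−(2p+5)/6)·ln det R`` on ``p(p−1)/2`` degrees of freedom.

Sample variances use the ``n−1`` denominator throughout.  The item count is
always taken from the data, never from a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CompletenessError, NumericError, ShapeError


@dataclass(frozen=True)
class PsychometricReport:
    alpha: float
    kmo_overall: float
    msa: dict[str, float]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def _as_array(items) -> tuple[np.ndarray, list[str]]:
    if isinstance(items, pd.DataFrame):
        values = items.to_numpy(dtype=float)
        labels = [str(c) for c in items.columns]
    else:
        values = np.asarray(items, dtype=float)
        labels = [f"item{i + 1}" for i in range(values.shape[1])] if values.ndim == 2 else []
    if values.ndim != 2:
        raise ShapeError("item matrix must be 2-dimensional (subjects × items)")
    n, p = values.shape
    if n < 3 or p < 2:
        raise ShapeError(f"need ≥3 subjects and ≥2 items, got {n}×{p}")
    if np.isnan(values).any():
        raise CompletenessError("item matrix contains missing cells")
    return values, labels


def cronbach_alpha(items) -> float:
    """Cronbach's α of a subjects × items matrix (n−1 variances)."""
    x, _ = _as_array(items)
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise NumericError("total-score variance is zero; α undefined")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def _correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise NumericError("an item has zero variance; correlations undefined")
    return np.corrcoef(x, rowvar=False)


def kmo(items) -> tuple[float, dict[str, float]]:
    """Kaiser–Meyer–Olkin sampling adequacy: overall value and per-item MSA.

    Partial correlations come from the scaled inverse correlation matrix:
    ``q_ij = −R⁻¹_ij / sqrt(R⁻¹_ii · R⁻¹_jj)``.
    """
    x, labels = _as_array(items)
    r = _correlation(x)
    cond = np.linalg.cond(r)
    if cond > 1e12:
        raise NumericError(
            f"correlation matrix is (near-)singular, condition number {cond:.3g}"
        )
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    q = -rinv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = r[off] ** 2
    q2 = q[off] ** 2
    overall = r2.sum() / (r2.sum() + q2.sum())
    msa = {}
    for i, label in enumerate(labels):
        mask = off[i]
        ri2 = (r[i, mask] ** 2).sum()
        qi2 = (q[i, mask] ** 2).sum()
        msa[label] = ri2 / (ri2 + qi2)
    return float(overall), msa


def bartlett_sphericity(items) -> tuple[float, int, float]:
    """Bartlett's test that the item correlation matrix is the identity."""
    x, _ = _as_array(items)
    n, p = x.shape
    if n <= p:
        raise ShapeError(f"need more subjects ({n}) than items ({p})")
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise NumericError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def battery(items) -> PsychometricReport:
    """Run the full reliability/validity battery on one item matrix."""
    alpha = cronbach_alpha(items)
    overall, msa = kmo(items)
    chi2, df, pval = bartlett_sphericity(items)
    return PsychometricReport(
        alpha=float(alpha),
        kmo_overall=overall,
        msa=msa,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
    )
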