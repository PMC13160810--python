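"""Bundled case-study data: an age-friendly community emergency station.

The package ships, as versioned CSV files, the published aggregate tables
of a needs-prioritization study of community health emergency stations for
older adults (19 requirement indicators in four dimensions, 351 valid
questionnaires, Kano category distributions, judgment matrices for a
must-be / one-dimensional / attractive hierarchy, four TRIZ conflicts, and
a two-alternative 7-point Likert evaluation matrix).  Loaders return the
package's domain objects so every stage can run offline.

Several published downstream numbers are internally inconsistent (category
distributions exceeding 100%, non-reciprocal judgment matrices, combined
weights that are not products of the printed layer weights, closeness
values violating the two-alternative identity).  The loaders carry the
values as printed; the pipeline recomputes each stage and records the
divergences explicitly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ahp import PairwiseMatrix
from .kano import KanoDistribution, from_counts
from .survey_io import Indicator, read_pairwise_matrix
from .topsis import EvaluationMatrix
from .triz import ConflictCase, ContradictionMatrix, load_matrix, load_parameters, read_conflicts


def _path(name: str) -> Path:
    with resources.as_file(resources.files("reqrank.data") / "casestudy" / name) as p:
        return Path(p)


def load_indicators() -> list[Indicator]:
    """The 19 requirement indicators (A1–A5, B1–B4, C1–C5, D1–D5)."""
    df = pd.read_csv(_path("indicators.csv"))
    return [
        Indicator(id=r.id, dimension=r.dimension, label=r.label)
        for r in df.itertuples(index=False)
    ]


def sample_accounting() -> pd.DataFrame:
    """Questionnaire sample counts: distribution/recovery, roles, demographics."""
    return pd.read_csv(_path("sample_accounting.csv"))


def sample_accounting_summary() -> dict[str, float]:
    """Derived sample statistics, computed from the raw counts.

    Recovery rate = valid/distributed; role counts must add up to the valid
    total; disease shares are over the valid sample.
    """
    df = sample_accounting()

    def count(category: str, level: str) -> int:
        sel = df[(df["category"] == category) & (df["level"] == level)]
        return int(sel["count"].iloc[0])

    distributed = count("questionnaires", "distributed")
    valid = count("questionnaires", "valid")
    older = count("role", "older_adult")
    caregiver = count("role", "caregiver")
    heart = count("disease", "heart_disease")
    return {
        "distributed": distributed,
        "valid": valid,
        "recovery_rate_pct": 100.0 * valid / distributed,
        "older_adult": older,
        "caregiver": caregiver,
        "role_total": older + caregiver,
        "heart_disease_pct": 100.0 * heart / valid,
    }


def kano_table() -> pd.DataFrame:
    """Published per-indicator category percentages with reported labels."""
    return pd.read_csv(_path("kano_distributions.csv"))


def kano_distributions(n_respondents: int = 351) -> list[KanoDistribution]:
    """Published category rows as distributions, renormalized to sum to one.

    Several printed rows do not add up to 100%, so renormalization is
    required before any rule can be applied.
    """
    df = kano_table()
    out = []
    for r in df.itertuples(index=False):
        counts = {"A": r.a_pct, "O": r.o_pct, "M": r.m_pct, "I": r.i_pct, "R": r.r_pct, "Q": r.q_pct}
        out.append(from_counts(r.indicator_id, counts, n_respondents=n_respondents))
    return out


def reported_kano_categories() -> dict[str, str]:
    """Demand types as published (M/O/A/I per indicator)."""
    df = kano_table()
    return dict(zip(df["indicator_id"], df["reported_category"]))


def criterion_matrix() -> PairwiseMatrix:
    """Criterion-layer judgment matrix over {M, O, A} (as printed, non-reciprocal)."""
    return read_pairwise_matrix(_path("pairwise_criteria.csv"))


def local_matrices() -> dict[str, PairwiseMatrix]:
    """Indicator-layer judgment matrices keyed by criterion (as printed).

    The must-be matrix is 7×7 (M1–M7), the one-dimensional 5×5 (O1–O5) and
    the attractive 4×4 (N1–N4), each as published.
    """
    return {
        "M": read_pairwise_matrix(_path("pairwise_must_be.csv")),
        "O": read_pairwise_matrix(_path("pairwise_one_dimensional.csv")),
        "A": read_pairwise_matrix(_path("pairwise_attractive.csv")),
    }


def reported_consistency() -> pd.DataFrame:
    """Published λmax / CI / CR per indicator-layer matrix."""
    return pd.read_csv(_path("consistency_reported.csv"))


def reported_weights() -> pd.DataFrame:
    """Published local and combined indicator weights with ranks."""
    return pd.read_csv(_path("reported_weights.csv"))


def reported_weight_vector() -> dict[str, float]:
    """Published combined weights renormalized to sum to one.

    The printed column sums to 2.268, so it cannot be used as-is; the
    renormalized vector is the weight input for the evaluation stage.
    """
    df = reported_weights()
    total = df["combined_weight"].sum()
    return {r.indicator: r.combined_weight / total for r in df.itertuples(index=False)}


def evaluation_matrix() -> EvaluationMatrix:
    """Published two-alternative initial evaluation matrix (15 indicators)."""
    df = pd.read_csv(_path("evaluation_matrix.csv"))
    indicators = tuple(df.columns[1:])
    return EvaluationMatrix(
        alternatives=tuple(df["alternative"]),
        indicators=indicators,
        values=df[list(indicators)].to_numpy(dtype=float),
    )


def triz_parameters():
    return load_parameters(_path("triz_parameters.csv"))


def contradiction_matrix() -> ContradictionMatrix:
    """Case-specific contradiction-matrix cells (nonstandard parameter numbering)."""
    return load_matrix(_path("contradiction_matrix.csv"), parameters=triz_parameters())


def conflicts() -> list[ConflictCase]:
    """The four design conflicts (two physical, two technical)."""
    return read_conflicts(_path("conflicts.csv"))
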