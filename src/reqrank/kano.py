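"""Kano model: classify paired functional/dysfunctional answers.

A respondent answers each requirement twice — "how would you feel if the
feature were present?" (functional) and "... if it were absent?"
(dysfunctional) — on the five-level scale like / must-be / neutral /
live-with / dislike.  The pair indexes a fixed 5×5 evaluation table whose
cells carry the six Kano categories:

* **A** attractive, **O** one-dimensional, **M** must-be, **I** indifferent,
* **R** reverse (respondent prefers the feature absent),
* **Q** questionable (contradictory answer pair).

The conventional evaluation table ships as an overridable CSV data file;
its cell counts are O:1, A:3, M:3, Q:2, R:7, I:9.  Final demand types are
assigned by maximum frequency over {A, O, M, I}; R and Q are reported but
never win the assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import CompletenessError, SchemaError
from .survey_io import ANSWER_LEVELS, ResponseTable

CATEGORIES: tuple[str, ...] = ("A", "O", "M", "I", "R", "Q")
#: Categories eligible to win the final assignment.
ASSIGNABLE: tuple[str, ...] = ("A", "O", "M", "I")
#: Default tie-break precedence (must-be first: safety-critical context).
DEFAULT_TIE_BREAK: tuple[str, ...] = ("M", "O", "A", "I")

EvaluationTable = Mapping[tuple[str, str], str]


def load_evaluation_table(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    """Load the 5×5 evaluation table (the packaged conventional table by default)."""
    import csv

    if path is None:
        ref = resources.files("reqrank.data") / "kano_evaluation_table.csv"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.reader(text.splitlines()))
    header = [c.strip() for c in rows[0][1:]]
    if tuple(header) != ANSWER_LEVELS or len(rows) != 6:
        raise SchemaError("evaluation table must be 5×5 over the standard answer levels")
    table: dict[tuple[str, str], str] = {}
    for row in rows[1:]:
        functional = row[0].strip()
        if functional not in ANSWER_LEVELS:
            raise SchemaError(f"unknown functional level {functional!r}")
        for dys, cell in zip(header, row[1:]):
            cat = cell.strip()
            if cat not in CATEGORIES:
                raise SchemaError(f"unknown category {cat!r} in evaluation table")
            table[(functional, dys)] = cat
    if len(table) != 25:
        raise SchemaError("evaluation table does not cover the 25-cell domain")
    return table


_DEFAULT_TABLE: dict[tuple[str, str], str] | None = None


def _default_table() -> dict[tuple[str, str], str]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_evaluation_table()
    return _DEFAULT_TABLE


def classify_pair(
    functional: str, dysfunctional: str, table: EvaluationTable | None = None
) -> str:
    """Classify one answer pair into A/O/M/I/R/Q via the evaluation table."""
    if functional not in ANSWER_LEVELS:
        raise SchemaError(f"functional answer {functional!r} outside 5-level domain")
    if dysfunctional not in ANSWER_LEVELS:
        raise SchemaError(f"dysfunctional answer {dysfunctional!r} outside 5-level domain")
    table = table if table is not None else _default_table()
    return table[(functional, dysfunctional)]


@dataclass(frozen=True)
class KanoDistribution:
    """Per-indicator category fractions with Better–Worse coordinates.

    Fractions sum to one; ``better``/``worse`` are None when no respondent
    fell in A/O/M/I (denominator zero).
    """

    indicator_id: str
    a: float
    o: float
    m: float
    i: float
    r: float
    q: float
    n_respondents: int
    better: float | None = None
    worse: float | None = None

    def __post_init__(self) -> None:
        total = self.a + self.o + self.m + self.i + self.r + self.q
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.indicator_id}: fractions sum to {total}, not 1")

    def fraction(self, category: str) -> float:
        return {"A": self.a, "O": self.o, "M": self.m, "I": self.i, "R": self.r, "Q": self.q}[
            category
        ]


@dataclass(frozen=True)
class KanoAssignment:
    indicator_id: str
    category: str
    rule: str
    tie_broken: bool = False


def better_worse(dist: KanoDistribution) -> tuple[float, float]:
    """Standard Better–Worse coefficients of a category distribution.

    Better = (A+O)/(A+O+M+I) estimates the satisfaction gain if the feature
    is present; Worse = −(O+M)/(A+O+M+I) the dissatisfaction if absent.
    R and Q are excluded from the denominator.
    """
    denom = dist.a + dist.o + dist.m + dist.i
    if denom <= 0:
        raise CompletenessError(
            f"{dist.indicator_id}: Better–Worse undefined (no A/O/M/I responses)"
        )
    return (dist.a + dist.o) / denom, -(dist.o + dist.m) / denom


def from_counts(
    indicator_id: str, counts: Mapping[str, float], n_respondents: int | None = None
) -> KanoDistribution:
    """Build a distribution from raw category counts (or unnormalized weights).

    Inputs are renormalized to sum to one, so published percentage rows that
    do not add up to exactly 100% can be carried as-is.
    """
    total = float(sum(counts.get(c, 0.0) for c in CATEGORIES))
    if total <= 0:
        raise CompletenessError(f"{indicator_id}: empty distribution")
    frac = {c: counts.get(c, 0.0) / total for c in CATEGORIES}
    dist = KanoDistribution(
        indicator_id=indicator_id,
        a=frac["A"],
        o=frac["O"],
        m=frac["M"],
        i=frac["I"],
        r=frac["R"],
        q=frac["Q"],
        n_respondents=int(n_respondents) if n_respondents is not None else 0,
    )
    if dist.a + dist.o + dist.m + dist.i > 0:
        b, w = better_worse(dist)
        dist = KanoDistribution(
            **{**dist.__dict__, "better": b, "worse": w}  # type: ignore[arg-type]
        )
    return dist


def tabulate(
    responses: ResponseTable, table: EvaluationTable | None = None
) -> list[KanoDistribution]:
    """Aggregate a response table into per-indicator category distributions.

    Fractions are over the respondents who answered that indicator;
    indicators with zero respondents are excluded with a warning.
    """
    import logging

    if not responses.records:
        raise CompletenessError("empty response table")
    table = table if table is not None else _default_table()
    counts: dict[str, dict[str, int]] = {}
    for rec in responses.records:
        cat = classify_pair(rec.functional, rec.dysfunctional, table)
        counts.setdefault(rec.indicator_id, {c: 0 for c in CATEGORIES})[cat] += 1
    out = []
    for indicator_id in sorted(counts):
        n = sum(counts[indicator_id].values())
        if n == 0:
            logging.getLogger("reqrank.kano").warning(
                "indicator %s has no respondents; excluded", indicator_id
            )
            continue
        out.append(from_counts(indicator_id, counts[indicator_id], n_respondents=n))
    return out


def assign_category(
    dist: KanoDistribution, tie_break: Sequence[str] = DEFAULT_TIE_BREAK
) -> KanoAssignment:
    """Assign the final demand type by maximum frequency over {A, O, M, I}.

    Ties are broken by the configured precedence (default M > O > A > I).
    The assignment is invariant to positive rescaling of the distribution.
    """
    if sorted(tie_break) != sorted(ASSIGNABLE):
        raise ValueError("tie_break must order exactly A, O, M, I")
    fracs = {c: dist.fraction(c) for c in ASSIGNABLE}
    best = max(fracs.values())
    if best <= 0:
        raise CompletenessError(
            f"{dist.indicator_id}: only R/Q responses — no assignable category"
        )
    winners = [c for c in ASSIGNABLE if fracs[c] == best]
    winner = min(winners, key=tie_break.index)
    return KanoAssignment(
        indicator_id=dist.indicator_id,
        category=winner,
        rule="max_frequency",
        tie_broken=len(winners) > 1,
    )


def category_sets(
    assignments: Iterable[KanoAssignment],
) -> tuple[dict[str, list[str]], list[str]]:
    """Group indicators by final category for the weighting hierarchy.

    Returns ``({"M": [...], "O": [...], "A": [...]}, excluded)`` where
    ``excluded`` lists the indifferent indicators, which do not enter the
    hierarchy.  Input order is preserved within groups.
    """
    groups: dict[str, list[str]] = {"M": [], "O": [], "A": []}
    excluded: list[str] = []
    for a in assignments:
        if a.category == "I":
            excluded.append(a.indicator_id)
        else:
            groups[a.category].append(a.indicator_id)
    return groups, excluded
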