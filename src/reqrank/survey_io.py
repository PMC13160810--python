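"""Readers, writers and validation for all tabular pipeline data.

The package defines its own long-format CSV schemas (RFC-4180, UTF-8,
``.`` decimal point):

* Kano questionnaires: ``respondent_id,role,indicator_id,functional,dysfunctional``
* Likert score files:  ``rater_id,rater_group,alternative_id,indicator_id,score``
* Pairwise judgment matrices: labeled square CSV; entries may be decimal
  numbers or fraction strings such as ``1/2``.

Every reader validates against the schema and either raises or, when a
logger is supplied in drop mode, logs-and-drops the offending row — rows
are never silently altered.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    ConfigurationError,
    IntegrityError,
    SchemaError,
    ShapeError,
)

logger = logging.getLogger("reqrank.io")

#: The five answer levels of a functional/dysfunctional Kano question pair.
ANSWER_LEVELS: tuple[str, ...] = ("like", "must_be", "neutral", "live_with", "dislike")

ROLES: tuple[str, ...] = ("older_adult", "caregiver")
RATER_GROUPS: tuple[str, ...] = ("expert", "user")

#: Indicator id prefix letter -> requirement dimension.
DIMENSIONS: Mapping[str, str] = {
    "A": "functional",
    "B": "appearance",
    "C": "culture_management",
    "D": "technical",
}

_FRACTION_RE = re.compile(r"^\d+/\d+$")


@dataclass(frozen=True)
class Indicator:
    """A requirement indicator such as ``A1`` (minimalist emergency call)."""

    id: str
    dimension: str
    label: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS.values():
            raise SchemaError(f"unknown dimension {self.dimension!r} for {self.id!r}")
        prefix = self.id[:1]
        if DIMENSIONS.get(prefix) != self.dimension:
            raise SchemaError(
                f"indicator id {self.id!r} does not match dimension {self.dimension!r}"
            )


@dataclass(frozen=True)
class ResponseRecord:
    respondent_id: str
    role: str
    indicator_id: str
    functional: str
    dysfunctional: str


@dataclass
class ResponseTable:
    """Validated respondent × indicator Kano answer pairs."""

    records: list[ResponseRecord]
    demographics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.respondent_id, rec.indicator_id)
            if key in seen:
                raise IntegrityError(f"duplicate (respondent, indicator) pair {key}")
            seen.add(key)
            if rec.functional not in ANSWER_LEVELS:
                raise SchemaError(f"answer {rec.functional!r} outside 5-level domain")
            if rec.dysfunctional not in ANSWER_LEVELS:
                raise SchemaError(f"answer {rec.dysfunctional!r} outside 5-level domain")
            if rec.role not in ROLES:
                raise SchemaError(f"unknown role {rec.role!r}")

    @property
    def respondents(self) -> list[str]:
        return sorted({r.respondent_id for r in self.records})

    @property
    def indicator_ids(self) -> list[str]:
        return sorted({r.indicator_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


@dataclass(frozen=True)
class ScoreRecord:
    rater_id: str
    rater_group: str
    alternative_id: str
    indicator_id: str
    score: int


@dataclass
class ScoreTable:
    """Rater-level 7-point Likert scores of design alternatives."""

    records: list[ScoreRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            key = (rec.rater_id, rec.alternative_id, rec.indicator_id)
            if key in seen:
                raise IntegrityError(f"duplicate score key {key}")
            seen.add(key)
            if not (isinstance(rec.score, (int, np.integer)) and 1 <= rec.score <= 7):
                raise SchemaError(f"score {rec.score!r} outside the 1-7 Likert scale")
            if rec.rater_group not in RATER_GROUPS:
                raise SchemaError(f"unknown rater_group {rec.rater_group!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def parse_ratio(token: str) -> float:
    """Parse a Saaty judgment entry: decimal or ``p/q`` fraction string."""
    token = token.strip()
    if _FRACTION_RE.match(token):
        num, den = token.split("/")
        if int(den) == 0:
            raise SchemaError(f"zero denominator in {token!r}")
        return int(num) / int(den)
    try:
        return float(token)
    except ValueError as exc:
        raise SchemaError(f"cannot parse judgment entry {token!r}") from exc


# ---------------------------------------------------------------------------
# Kano questionnaire files
# ---------------------------------------------------------------------------

_KANO_HEADER = ["respondent_id", "role", "indicator_id", "functional", "dysfunctional"]


def read_kano_responses(
    path: str | Path,
    indicators: Iterable[Indicator | str] | None = None,
    *,
    on_bad_row: str = "raise",
) -> ResponseTable:
    """Read a long-format Kano questionnaire CSV.

    Parameters
    ----------
    indicators:
        The indicator set the file must resolve against; ids or
        :class:`Indicator` objects. ``None`` skips the cross-reference check.
    on_bad_row:
        ``"raise"`` (default) or ``"drop"`` — dropped rows are logged with
        their line number, never silently altered.
    """
    path = Path(path)
    known: set[str] | None = None
    if indicators is not None:
        known = {i.id if isinstance(i, Indicator) else str(i) for i in indicators}

    records: list[ResponseRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _KANO_HEADER:
            raise SchemaError(
                f"{path}: header {reader.fieldnames} != expected {_KANO_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = ResponseRecord(
                    respondent_id=row["respondent_id"],
                    role=row["role"],
                    indicator_id=row["indicator_id"],
                    functional=row["functional"],
                    dysfunctional=row["dysfunctional"],
                )
                if rec.functional not in ANSWER_LEVELS:
                    raise SchemaError(
                        f"{path}:{lineno}: answer {rec.functional!r} not in 5-level domain"
                    )
                if rec.dysfunctional not in ANSWER_LEVELS:
                    raise SchemaError(
                        f"{path}:{lineno}: answer {rec.dysfunctional!r} not in 5-level domain"
                    )
                if rec.role not in ROLES:
                    raise SchemaError(f"{path}:{lineno}: unknown role {rec.role!r}")
                if known is not None and rec.indicator_id not in known:
                    raise SchemaError(
                        f"{path}:{lineno}: unknown indicator id {rec.indicator_id!r}"
                    )
            except SchemaError:
                if on_bad_row == "drop":
                    logger.warning("dropping malformed row at %s:%d", path, lineno)
                    continue
                raise
            records.append(rec)

    table = ResponseTable(records)
    logger.info(
        "read %d kano records (%d respondents, %d indicators) from %s",
        len(records),
        len(table.respondents),
        len(table.indicator_ids),
        path,
    )
    return table


def write_kano_responses(table: ResponseTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_KANO_HEADER)
        for rec in table.records:
            writer.writerow(
                [rec.respondent_id, rec.role, rec.indicator_id, rec.functional, rec.dysfunctional]
            )


# ---------------------------------------------------------------------------
# Likert score files
# ---------------------------------------------------------------------------

_SCORE_HEADER = ["rater_id", "rater_group", "alternative_id", "indicator_id", "score"]


def read_scores(path: str | Path) -> ScoreTable:
    """Read a long-format 7-point Likert score CSV."""
    path = Path(path)
    records: list[ScoreRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _SCORE_HEADER:
            raise SchemaError(
                f"{path}: header {reader.fieldnames} != expected {_SCORE_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                score = int(row["score"])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-integer score {row['score']!r}") from exc
            if not 1 <= score <= 7:
                raise SchemaError(f"{path}:{lineno}: score {score} outside 1-7")
            if row["rater_group"] not in RATER_GROUPS:
                raise SchemaError(
                    f"{path}:{lineno}: unknown rater_group {row['rater_group']!r}"
                )
            records.append(
                ScoreRecord(
                    rater_id=row["rater_id"],
                    rater_group=row["rater_group"],
                    alternative_id=row["alternative_id"],
                    indicator_id=row["indicator_id"],
                    score=score,
                )
            )
    table = ScoreTable(records)
    counts = pd.Series([r.rater_group for r in records]).value_counts().to_dict() if records else {}
    logger.info("read %d score records from %s (per-group: %s)", len(records), path, counts)
    return table


def write_scores(table: ScoreTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCORE_HEADER)
        for rec in table.records:
            writer.writerow(
                [rec.rater_id, rec.rater_group, rec.alternative_id, rec.indicator_id, rec.score]
            )


# ---------------------------------------------------------------------------
# Pairwise judgment matrices
# ---------------------------------------------------------------------------


def read_pairwise_matrix(path: str | Path):
    """Read a labeled square CSV of Saaty ratio judgments.

    Entries may be decimals or fraction strings (``1/3`` → 0.333...).
    Labels are preserved in file order. Returns an :class:`~reqrank.ahp.PairwiseMatrix`.
    """
    from .ahp import PairwiseMatrix  # local import to avoid a cycle

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SchemaError(f"{path}: empty file")
    labels = [c.strip() for c in rows[0][1:]]
    n = len(labels)
    if len(rows) - 1 != n:
        raise ShapeError(f"{path}: {len(rows) - 1} rows for {n} columns — matrix not square")
    values = np.empty((n, n), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != n + 1:
            raise ShapeError(f"{path}: row {i + 2} has {len(row) - 1} entries, expected {n}")
        if row[0].strip() != labels[i]:
            raise SchemaError(
                f"{path}: row label {row[0]!r} does not match column label {labels[i]!r}"
            )
        for j, token in enumerate(row[1:]):
            v = parse_ratio(token)
            if v <= 0:
                raise SchemaError(f"{path}: non-positive entry {token!r} at ({i}, {j})")
            values[i, j] = v
    return PairwiseMatrix(items=tuple(labels), values=values)


def write_pairwise_matrix(matrix, path: str | Path) -> None:
    """Write a pairwise matrix as labeled CSV with round-tripping floats."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(matrix.items))
        for label, row in zip(matrix.items, matrix.values):
            writer.writerow([label] + [repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# Subjects × items matrices for psychometrics
# ---------------------------------------------------------------------------


def read_item_matrix(path: str | Path) -> pd.DataFrame:
    """Read a subjects × items CSV (header = item labels) for psychometrics."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise CompletenessError(f"{path}: missing cells in item matrix")
    return df


def write_item_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration and reports
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run."""

    kano_responses: str | None = None
    item_matrix: str | None = None
    criterion_matrix: str | None = None
    local_matrices: dict[str, str] = field(default_factory=dict)  # category -> path
    scores: str | None = None
    conflicts: str | None = None
    contradiction_matrix: str | None = None
    triz_parameters: str | None = None
    indicators: str | None = None
    tie_break: tuple[str, ...] = ("M", "O", "A", "I")
    ahp_method: str = "eigenvector"
    reciprocity: str = "repair_upper"
    directions: dict[str, str] = field(default_factory=dict)  # indicator -> benefit/cost
    seed: int = 0
    output_dir: str = "reqrank_out"
    precision: int = 6

    def __post_init__(self) -> None:
        if self.ahp_method not in ("eigenvector", "geometric_mean"):
            raise ConfigurationError(f"unknown AHP method {self.ahp_method!r}")
        if self.reciprocity not in ("strict", "repair_upper"):
            raise ConfigurationError(f"unknown reciprocity mode {self.reciprocity!r}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ConfigurationError("seed must be a non-negative integer")
        if sorted(self.tie_break) != ["A", "I", "M", "O"]:
            raise ConfigurationError("tie_break must be an ordering of A, O, M, I")

    def validate_paths(self) -> None:
        for name in (
            "kano_responses",
            "item_matrix",
            "criterion_matrix",
            "scores",
            "conflicts",
            "contradiction_matrix",
            "triz_parameters",
            "indicators",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"configured file {name}={value!r} does not exist")
        for cat, p in self.local_matrices.items():
            if not Path(p).exists():
                raise ConfigurationError(f"local matrix for {cat!r} at {p!r} does not exist")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = json.load(fh)
        if "tie_break" in raw:
            raw["tie_break"] = tuple(raw["tie_break"])
        return cls(**raw)


def _round_floats(obj, precision: int):
    if isinstance(obj, float):
        return round(obj, precision)
    if isinstance(obj, dict):
        return {k: _round_floats(v, precision) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, precision) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), precision)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), precision)
    return obj


def write_report(results: Mapping, out_dir: str | Path, *, precision: int = 6) -> Path:
    """Write the machine-readable pipeline report.

    One JSON file (``report.json``, keys sorted, floats at the configured
    precision) plus one CSV per stage table found under a ``tables`` key.
    Identical inputs produce byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _round_floats(dict(results), precision)
    tables = payload.pop("tables", {})
    report_path = out_dir / "report.json"
    with report_path.open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, table in tables.items():
        df = pd.DataFrame(table)
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format=f"%.{precision}g")
    return report_path
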