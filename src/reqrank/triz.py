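"""TRIZ contradiction handling: parameters, inventive principles, lookup.

A *technical* contradiction improves one engineering parameter while
worsening another and is resolved by looking the pair up in a contradiction
matrix; a *physical* contradiction demands opposite states of one parameter
and carries its principle set directly (it has no matrix cell).  Parameter
lists and the matrix are loadable data files, so nonstandard numberings can
ship alongside the classical one.  Principle id order is preserved — it may
encode priority.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError

CONFLICT_TYPES = ("physical", "technical")


@dataclass(frozen=True)
class TrizParameter:
    id: int
    name: str


@dataclass(frozen=True)
class InventivePrinciple:
    id: int
    name: str

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 40:
            raise SchemaError(f"inventive principle id {self.id} outside 1-40")


@dataclass(frozen=True)
class ConflictCase:
    """One design contradiction with its resolved inventive principles."""

    label: str
    conflict_type: str
    improving: str  # parameter id (technical) or free-text state (physical)
    worsening: str
    indicators: tuple[str, ...] = ()
    principles: tuple[int, ...] = ()
    provenance: str = ""  # "matrix" or "configured"

    def __post_init__(self) -> None:
        if self.conflict_type not in CONFLICT_TYPES:
            raise SchemaError(f"unknown conflict type {self.conflict_type!r}")


class ContradictionMatrix:
    """Immutable (improving id, worsening id) → principle id list lookup."""

    def __init__(self, cells: Mapping[tuple[int, int], Sequence[int]]):
        self._cells = {k: tuple(v) for k, v in cells.items()}

    def lookup(self, improving: int, worsening: int) -> tuple[int, ...]:
        return self._cells.get((improving, worsening), ())

    def __len__(self) -> int:
        return len(self._cells)

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self._cells


def _parse_principles(token: str) -> tuple[int, ...]:
    token = token.strip()
    if not token:
        return ()
    return tuple(int(t) for t in token.replace(",", ";").split(";") if t.strip())


def load_principles(path: str | Path | None = None) -> dict[int, InventivePrinciple]:
    """Load the inventive-principle name list (classical 40 by default)."""
    if path is None:
        text = (resources.files("reqrank.data") / "triz_principles.csv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    out = {}
    for row in csv.DictReader(text.splitlines()):
        p = InventivePrinciple(id=int(row["id"]), name=row["name"])
        out[p.id] = p
    return out


def load_parameters(path: str | Path) -> dict[int, TrizParameter]:
    text = Path(path).read_text("utf-8")
    out: dict[int, TrizParameter] = {}
    for lineno, row in enumerate(csv.DictReader(text.splitlines()), start=2):
        pid = int(row["id"])
        if pid in out:
            raise SchemaError(f"{path}:{lineno}: duplicate parameter id {pid}")
        out[pid] = TrizParameter(id=pid, name=row["name"])
    return out


def load_matrix(
    path: str | Path, parameters: Mapping[int, TrizParameter] | None = None
) -> ContradictionMatrix:
    """Load a contradiction matrix from CSV (``improving,worsening,principles``).

    ``principles`` cells are ``;``-separated ids; missing cells are simply
    absent rows.  Duplicate (improving, worsening) keys are a parse error.
    """
    text = Path(path).read_text("utf-8")
    cells: dict[tuple[int, int], tuple[int, ...]] = {}
    for lineno, row in enumerate(csv.DictReader(text.splitlines()), start=2):
        try:
            key = (int(row["improving"]), int(row["worsening"]))
            principles = _parse_principles(row["principles"])
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}:{lineno}: malformed matrix row") from exc
        if key in cells:
            raise SchemaError(f"{path}:{lineno}: duplicate matrix cell {key}")
        if parameters is not None:
            for pid in key:
                if pid not in parameters:
                    raise SchemaError(f"{path}:{lineno}: unknown parameter id {pid}")
        cells[key] = principles
    return ContradictionMatrix(cells)


def read_conflicts(path: str | Path) -> list[ConflictCase]:
    """Read conflict cases from CSV.

    Physical cases carry their configured principle set in the
    ``principles`` column; technical cases normally leave it empty and are
    filled by :func:`resolve`.
    """
    text = Path(path).read_text("utf-8")
    cases = []
    for row in csv.DictReader(text.splitlines()):
        cases.append(
            ConflictCase(
                label=row["label"],
                conflict_type=row["conflict_type"],
                improving=row["improving"].strip(),
                worsening=row["worsening"].strip(),
                indicators=tuple(t for t in row["indicators"].split(";") if t),
                principles=_parse_principles(row.get("principles", "")),
                provenance="configured" if row.get("principles", "").strip() else "",
            )
        )
    return cases


def resolve(case: ConflictCase, matrix: ContradictionMatrix) -> ConflictCase:
    """Fill a case's principle set.

    Technical conflicts are looked up in the matrix (empty cell → warning
    and empty list); physical conflicts keep their configured set.
    """
    import logging

    if case.conflict_type == "physical":
        return replace(case, provenance="configured")
    improving, worsening = int(case.improving), int(case.worsening)
    principles = matrix.lookup(improving, worsening)
    if not principles:
        logging.getLogger("reqrank.triz").warning(
            "no matrix cell for (%d, %d) in case %r", improving, worsening, case.label
        )
    return replace(case, principles=principles, provenance="matrix")


def report_conflicts(
    cases: Iterable[ConflictCase],
    principles: Mapping[int, InventivePrinciple] | None = None,
) -> pd.DataFrame:
    """Tabulate resolved conflicts with principle ids mapped to names."""
    principles = principles if principles is not None else load_principles()
    rows = []
    for case in cases:
        names = []
        for pid in case.principles:
            if pid not in principles:
                raise SchemaError(f"no name for inventive principle {pid}")
            names.append(principles[pid].name)
        rows.append(
            {
                "label": case.label,
                "conflict_type": case.conflict_type,
                "improving": case.improving,
                "worsening": case.worsening,
                "indicators": ";".join(case.indicators),
                "principles": ";".join(str(p) for p in case.principles),
                "principle_names": ";".join(names),
                "provenance": case.provenance,
            }
        )
    columns = [
        "label",
        "conflict_type",
        "improving",
        "worsening",
        "indicators",
        "principles",
        "principle_names",
        "provenance",
    ]
    return pd.DataFrame(rows, columns=columns)
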