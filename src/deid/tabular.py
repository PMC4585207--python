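"""Demographic/behavioral table handling for de-identification.

The table is a delimited text file (TSV or CSV) whose first row is a
header and whose first column holds the subject ID.  Cells are typed on
load (numeric strings become numbers; empty/"NA"/"NaN"/"N/A"/"." become
the MISSING sentinel).  Operations here audit the table (missing cells,
likely identifier columns), drop columns, and generalize quasi-
identifiers by rounding/banding — the standard disclosure-limitation
moves for continuous attributes like height or age.
"""

from __future__ import annotations

import csv
import math
import os
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DuplicateIdError, TableError


class _Missing:
    """Singleton sentinel for a missing cell (distinct from 0, "", NaN)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"


MISSING = _Missing()

#: tokens recognized as missing on input (case-insensitive for na/nan)
MISSING_TOKENS = {"", "na", "nan", "n/a", "."}


def _type_cell(token: str) -> object:
    t = token.strip()
    if t.lower() in MISSING_TOKENS:
        return MISSING
    try:
        return int(t)
    except ValueError:
        pass
    try:
        f = float(t)
    except ValueError:
        return t
    return f if math.isfinite(f) else t


def _format_cell(value: object, missing_code: str) -> str:
    if value is MISSING:
        return missing_code
    if isinstance(value, float):
        return repr(value) if value != int(value) else str(int(value))
    return str(value)


@dataclass(frozen=True)
class CellRef:
    row: int
    column: int


class FindingReason(Enum):
    NAME_PATTERN = "name_pattern"
    DATE_VALUES = "date_values"
    ID_LABEL = "id_label"
    USER = "user"


@dataclass(frozen=True)
class IdentifierFinding:
    column: str
    reason: FindingReason
    note: str = ""


class GeneralizationKind(Enum):
    BIN_ROUND = "bin_round"
    SIG_FIGS = "sig_figs"
    RANGE_BAND = "range_band"


@dataclass(frozen=True)
class GeneralizationRule:
    column: str
    kind: GeneralizationKind
    parameter: float

    def __post_init__(self):
        if self.parameter <= 0:
            raise TableError("generalization parameter must be > 0")


@dataclass(frozen=True)
class DatasetTable:
    """Ordered, typed demographic table; column 0 is the subject ID."""

    column_names: tuple[str, ...]
    rows: tuple[tuple[object, ...], ...]
    missing_code: str = "NA"

    def __post_init__(self):
        arity = len(self.column_names)
        for i, r in enumerate(self.rows):
            if len(r) != arity:
                raise TableError(f"row {i} has {len(r)} cells; expected {arity}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(str(r[0]) for r in self.rows)

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise TableError(f"no column named {name!r}") from None

    def column(self, name: str) -> tuple[object, ...]:
        j = self.column_index(name)
        return tuple(r[j] for r in self.rows)

    def validate_ids(self) -> None:
        seen: set[str] = set()
        for i, r in enumerate(self.rows):
            v = r[0]
            if v is MISSING:
                raise TableError(f"row {i}: missing subject ID")
            key = str(v)
            if key in seen:
                raise DuplicateIdError(f"duplicate subject ID {key!r}")
            seen.add(key)


def _sniff_delimiter(sample: str) -> str:
    # Prefer tab when present; CSV otherwise.
    first = sample.splitlines()[0] if sample else ""
    return "\t" if "\t" in first else ","


def load_table(path: str | os.PathLike, delimiter: str | None = None) -> DatasetTable:
    """Load a delimited text table and type its cells."""
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    reader = csv.reader(text.splitlines(), delimiter=delimiter)
    recs = list(reader)
    if not recs:
        raise TableError(f"{p}: empty file")
    header = tuple(h.strip() for h in recs[0])
    rows = []
    for i, rec in enumerate(recs[1:]):
        if len(rec) != len(header):
            raise TableError(
                f"{p}: row {i + 1} has {len(rec)} cells; header has {len(header)}"
            )
        rows.append(tuple(_type_cell(c) for c in rec))
    table = DatasetTable(column_names=header, rows=tuple(rows))
    table.validate_ids()
    return table


def write_table(
    table: DatasetTable, path: str | os.PathLike, delimiter: str = "\t"
) -> Path:
    """Write the table as delimited text; MISSING becomes the missing code."""
    p = Path(path)
    with open(p, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(table.column_names)
        for r in table.rows:
            w.writerow([_format_cell(c, table.missing_code) for c in r])
    return p


def find_missing(table: DatasetTable) -> list[CellRef]:
    """All MISSING cells in row-major order."""
    return [
        CellRef(i, j)
        for i, r in enumerate(table.rows)
        for j, c in enumerate(r)
        if c is MISSING
    ]


#: column-name fragments that flag a likely direct identifier
IDENTIFIER_NAME_PATTERNS = (
    "id", "name", "dob", "birth", "date", "address", "phone", "ssn",
    "mrn", "email", "zip",
)

_DATE_PATTERNS = (
    re.compile(r"^\d{4}-\d{1,2}-\d{1,2}$"),      # ISO
    re.compile(r"^\d{1,2}/\d{1,2}/\d{4}$"),       # US or European slash form
    re.compile(r"^\d{1,2}-\d{1,2}-\d{4}$"),
)


def _looks_like_date(value: object) -> bool:
    return isinstance(value, str) and any(p.match(value) for p in _DATE_PATTERNS)


def detect_identifier_columns(
    table: DatasetTable,
    name_patterns: Sequence[str] = IDENTIFIER_NAME_PATTERNS,
    date_fraction: float = 0.8,
) -> list[IdentifierFinding]:
    """Flag likely identifier columns.

    A column is flagged when its name contains a configured identifier
    fragment (case-insensitive), or when at least ``date_fraction`` of
    its non-missing values parse as calendar dates.  Column 0 is always
    flagged as the ID label.  Deterministic and side-effect free.
    """
    findings: list[IdentifierFinding] = []
    for j, name in enumerate(table.column_names):
        if j == 0:
            findings.append(
                IdentifierFinding(name, FindingReason.ID_LABEL, "subject-ID column")
            )
            continue
        lowered = name.lower()
        hit = next((p for p in name_patterns if p in lowered), None)
        if hit is not None:
            findings.append(
                IdentifierFinding(
                    name, FindingReason.NAME_PATTERN, f"column name contains {hit!r}"
                )
            )
            continue
        values = [r[j] for r in table.rows if r[j] is not MISSING]
        if values:
            frac = sum(_looks_like_date(v) for v in values) / len(values)
            if frac >= date_fraction:
                findings.append(
                    IdentifierFinding(
                        name,
                        FindingReason.DATE_VALUES,
                        f"{frac:.0%} of values parse as dates",
                    )
                )
    return findings


def drop_columns(
    table: DatasetTable, columns: Iterable[str], allow_id: bool = False
) -> DatasetTable:
    """Return a new table without the named columns; the source is untouched."""
    names = list(columns)
    idx = {table.column_index(n) for n in names}
    if 0 in idx and not allow_id:
        raise TableError(
            "refusing to drop the subject-ID column before an ID map exists"
        )
    keep = [j for j in range(len(table.column_names)) if j not in idx]
    return replace(
        table,
        column_names=tuple(table.column_names[j] for j in keep),
        rows=tuple(tuple(r[j] for j in keep) for r in table.rows),
    )


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def _sig_figs(x: float, s: int) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - s + 1)
    return _round_half_away(x / scale) * scale


def generalize_column(table: DatasetTable, rule: GeneralizationRule) -> DatasetTable:
    """Coarsen a numeric column to reduce re-identification risk.

    BIN_ROUND rounds to the nearest multiple of the bin width (half away
    from zero); SIG_FIGS keeps a fixed number of significant figures;
    RANGE_BAND replaces the value with the label of its half-open band
    "[k*w, (k+1)*w)".  MISSING cells pass through unchanged.
    """
    j = table.column_index(rule.column)
    w = rule.parameter
    new_rows = []
    for i, r in enumerate(table.rows):
        cell = r[j]
        if cell is MISSING:
            new_rows.append(r)
            continue
        if not isinstance(cell, (int, float)) or isinstance(cell, bool):
            raise TableError(
                f"cell ({i}, {rule.column}) is not numeric: {cell!r}"
            )
        x = float(cell)
        if rule.kind is GeneralizationKind.BIN_ROUND:
            v = _round_half_away(x / w) * w
            out: object = int(v) if v == int(v) else v
        elif rule.kind is GeneralizationKind.SIG_FIGS:
            v = _sig_figs(x, int(w))
            out = int(v) if v == int(v) else v
        else:  # RANGE_BAND
            k = math.floor(x / w)
            lo, hi = k * w, (k + 1) * w
            fmt = lambda b: str(int(b)) if b == int(b) else repr(b)
            out = f"[{fmt(lo)}, {fmt(hi)})"
        new_rows.append(tuple(out if jj == j else c for jj, c in enumerate(r)))
    return replace(table, rows=tuple(new_rows))
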