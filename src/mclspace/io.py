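"""Delimited-text I/O for compound tables and measurable-compound-list (MCL) files.

Conventions:

* delimiter auto-detected among comma / tab / semicolon from the header row
  (override with ``delimiter=``);
* decimal separator is ``.`` only — a decimal comma raises ValidationError
  instead of silently corrupting values;
* blank cells mean "absent", to be computed or predicted downstream.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ValidationError

#: precomputed fields parsed as integers (counts / class codes)
INT_FIELDS = frozenset({"hbd", "hba", "mobility_class"})
#: precomputed fields parsed as reals
FLOAT_FIELDS = frozenset({"mw", "xlogp", "tpsa", "log_ie", "ri"})
PRECOMPUTED_FIELDS = INT_FIELDS | FLOAT_FIELDS

MCL_COLUMNS = (
    "id",
    "smiles",
    "polarity",
    "mobility_class",
    "log_ie",
    "predicted_ri",
    "rplc_class",
    "cell_index",
    "rank",
)


@dataclass(frozen=True)
class CompoundRecord:
    """One input structure: id, SMILES and any precomputed descriptor values."""

    id: str
    smiles: str
    inchikey: str | None = None
    precomputed: dict[str, float | int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.smiles:
            raise ValidationError(f"record {self.id!r}: empty SMILES")
        for name in INT_FIELDS & self.precomputed.keys():
            v = self.precomputed[name]
            if v != int(v) or v < 0:
                raise ValidationError(
                    f"record {self.id!r}: field {name} must be a non-negative integer, got {v!r}"
                )
        mob = self.precomputed.get("mobility_class")
        if mob is not None and mob not in (1, 2, 3):
            raise ValidationError(
                f"record {self.id!r}: mobility_class must be 1, 2 or 3, got {mob!r}"
            )


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names to input column headers.

    ``id`` and ``smiles`` are mandatory; any canonical field left unmapped is
    computed or predicted downstream.
    """

    id: str
    smiles: str
    inchikey: str | None = None
    precomputed: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id or not self.smiles:
            raise ConfigurationError("column map must define both 'id' and 'smiles'")
        unknown = set(self.precomputed) - PRECOMPUTED_FIELDS
        if unknown:
            raise ConfigurationError(f"unknown precomputed fields: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "ColumnMap":
        mapping = dict(mapping)
        if "id" not in mapping or "smiles" not in mapping:
            raise ConfigurationError("column map must define both 'id' and 'smiles'")
        return cls(
            id=mapping.pop("id"),
            smiles=mapping.pop("smiles"),
            inchikey=mapping.pop("inchikey", None),
            precomputed=mapping,
        )


def detect_delimiter(header_line: str) -> str:
    """Pick the delimiter among ',', tab, ';' splitting the header into most fields."""
    counts = {d: header_line.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=lambda d: counts[d])
    return best if counts[best] > 0 else ","


def _parse_number(raw: str, fieldname: str, row_number: int):
    text = raw.strip()
    if not text:
        return None
    if "," in text:
        raise ValidationError(
            f"row {row_number}: field {fieldname!r} contains a comma ({raw!r}); "
            "decimal separator must be '.'"
        )
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(
            f"row {row_number}: cannot parse {fieldname!r} value {raw!r} as a number"
        ) from None
    if not math.isfinite(value):
        raise ValidationError(f"row {row_number}: non-finite {fieldname!r} value {raw!r}")
    if fieldname in INT_FIELDS:
        if value != int(value):
            raise ValidationError(
                f"row {row_number}: field {fieldname!r} must be an integer, got {raw!r}"
            )
        return int(value)
    return value


def read_compound_table(
    path: str | Path,
    colmap: ColumnMap,
    delimiter: str | None = None,
) -> list[CompoundRecord]:
    """Read a delimited compound table into records, preserving row order.

    Raises ConfigurationError if mapped id/smiles columns are absent from the
    header and ValidationError on duplicate ids (citing both rows) or
    unparseable numeric cells (citing the row).
    """
    path = Path(path)
    with path.open(newline="") as handle:
        header_line = handle.readline()
        if not header_line:
            raise ValidationError(f"{path}: empty file")
        delim = delimiter or detect_delimiter(header_line)
        header = next(csv.reader([header_line], delimiter=delim))
        required = {"id": colmap.id, "smiles": colmap.smiles}
        for canonical, column in required.items():
            if column not in header:
                raise ConfigurationError(
                    f"{path}: missing mandatory {canonical} column {column!r}"
                )
        reader = csv.DictReader(handle, fieldnames=header, delimiter=delim)
        records: list[CompoundRecord] = []
        first_row_of: dict[str, int] = {}
        for row_number, row in enumerate(reader, start=2):  # header is row 1
            rid = (row.get(colmap.id) or "").strip()
            if not rid:
                raise ValidationError(f"row {row_number}: empty id")
            if rid in first_row_of:
                raise ValidationError(
                    f"duplicate id {rid!r} in rows {first_row_of[rid]} and {row_number}"
                )
            first_row_of[rid] = row_number
            smiles = (row.get(colmap.smiles) or "").strip()
            if not smiles:
                raise ValidationError(f"row {row_number}: record {rid!r} has empty SMILES")
            inchikey = None
            if colmap.inchikey and colmap.inchikey in row:
                inchikey = (row[colmap.inchikey] or "").strip() or None
            precomputed: dict[str, float | int] = {}
            for fieldname, column in colmap.precomputed.items():
                value = _parse_number(row.get(column) or "", fieldname, row_number)
                if value is not None:
                    precomputed[fieldname] = value
            records.append(
                CompoundRecord(id=rid, smiles=smiles, inchikey=inchikey, precomputed=precomputed)
            )
    return records


@dataclass(frozen=True)
class MCLEntry:
    """One selected candidate of a measurable compound list."""

    id: str
    smiles: str
    polarity: str  # "positive" | "negative"
    mobility_class: int
    log_ie: float
    predicted_ri: float | None
    rplc_class: int | None
    cell_index: tuple[int, ...]
    rank: int

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(f"invalid polarity {self.polarity!r}")
        if self.mobility_class not in (1, 2, 3):
            raise ValidationError(f"invalid mobility_class {self.mobility_class!r}")
        if self.rank < 1:
            raise ValidationError("rank must be 1-based")


def _format_real(value: float | None) -> str:
    if value is None:
        return ""
    return format(float(value), ".17g")


def write_mcl(path: str | Path, entries: Sequence[MCLEntry]) -> None:
    """Write one polarity's MCL as CSV, rows sorted by rank ascending."""
    polarities = {e.polarity for e in entries}
    if len(polarities) > 1:
        raise ValidationError(f"mixed polarities in one MCL file: {sorted(polarities)}")
    ordered = sorted(entries, key=lambda e: e.rank)
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(MCL_COLUMNS)
        for e in ordered:
            writer.writerow(
                [
                    e.id,
                    e.smiles,
                    e.polarity,
                    e.mobility_class,
                    _format_real(e.log_ie),
                    _format_real(e.predicted_ri),
                    "" if e.rplc_class is None else e.rplc_class,
                    "|".join(str(i) for i in e.cell_index),
                    e.rank,
                ]
            )


def read_mcl(path: str | Path) -> list[MCLEntry]:
    """Read an MCL file written by :func:`write_mcl` (round-trips all fields)."""
    with Path(path).open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or tuple(reader.fieldnames) != MCL_COLUMNS:
            raise ValidationError(f"{path}: not an MCL file (unexpected header)")
        entries = []
        for row in reader:
            entries.append(
                MCLEntry(
                    id=row["id"],
                    smiles=row["smiles"],
                    polarity=row["polarity"],
                    mobility_class=int(row["mobility_class"]),
                    log_ie=float(row["log_ie"]),
                    predicted_ri=float(row["predicted_ri"]) if row["predicted_ri"] else None,
                    rplc_class=int(row["rplc_class"]) if row["rplc_class"] else None,
                    cell_index=tuple(int(t) for t in row["cell_index"].split("|")) if row["cell_index"] else (),
                    rank=int(row["rank"]),
                )
            )
    return entries


def write_table(path: str | Path, rows: Iterable[Mapping[str, object]], columns: Sequence[str]) -> None:
    """Small helper for writing plain CSV tables with a fixed column order."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row.get(c, "") for c in columns])
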