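"""Subject-level cohort data model and tidy CSV round-trip.

A cohort is one row per child: study group (neurotypical control vs ASD),
sex, age, Bristol Stool Chart type, urinary creatinine, and the five
urinary uremic-toxin analytes (ADMA, SDMA, TMAO, IS, PCS).  Toxin values
are carried either raw (µmol/L urine) or creatinine-normalized
(µmol/mmol creatinine); the unit state is explicit and must be uniform
across a table.

Missing cells are encoded as the empty string and below-limit-of-
quantification cells as ``"<LOQ"`` so that write → read is the identity
on validated tables.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

ANALYTES = ("ADMA", "SDMA", "TMAO", "IS", "PCS")

GROUPS = ("control", "asd")
SEXES = ("boy", "girl", "unknown")

RAW = "raw_umol_per_L"
NORMALIZED = "normalized_umol_per_mmol"
UNIT_STATES = (RAW, NORMALIZED)

FLAG_OK = "ok"
FLAG_BELOW_LOQ = "below_loq"
FLAG_MISSING = "missing"

MISSING_SENTINEL = ""
LOQ_SENTINEL = "<LOQ"

#: canonical column order of the CSV dialect
COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "age_years",
    "bsc_type",
    "creatinine",
    "unit_state",
) + ANALYTES


class CohortError(ValueError):
    """Fatal, table-level validation failure."""


@dataclass(frozen=True)
class ToxinEntry:
    """One analyte measurement: value (None unless flag == ok) + flag."""

    value: float | None
    flag: str = FLAG_OK

    def __post_init__(self) -> None:
        if self.flag not in (FLAG_OK, FLAG_BELOW_LOQ, FLAG_MISSING):
            raise CohortError(f"unknown toxin flag {self.flag!r}")
        if self.flag == FLAG_OK:
            if self.value is None or self.value < 0:
                raise CohortError("ok-flagged toxin requires a non-negative value")
        elif self.value is not None:
            raise CohortError(f"{self.flag}-flagged toxin must not carry a value")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    sex: str
    age_years: float
    bsc_type: int | None
    creatinine: float | None  # mmol/L, None when not measured
    toxins: Mapping[str, ToxinEntry]
    unit_state: str = NORMALIZED
    normalization_excluded: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise CohortError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_years < 0:
            raise CohortError("age_years must be non-negative")
        if self.bsc_type is not None and self.bsc_type not in range(1, 8):
            raise CohortError(f"bsc_type must be in 1..7, got {self.bsc_type}")
        if self.creatinine is not None and self.creatinine <= 0:
            raise CohortError("creatinine, when present, must be positive")
        if self.unit_state not in UNIT_STATES:
            raise CohortError(f"unknown unit_state {self.unit_state!r}")
        missing = set(ANALYTES) - set(self.toxins)
        if missing:
            raise CohortError(f"record {self.subject_id}: analytes missing entries: {sorted(missing)}")

    def toxin_value(self, analyte: str) -> float | None:
        entry = self.toxins[analyte]
        return entry.value if entry.flag == FLAG_OK else None


@dataclass
class RowDiagnostic:
    """One rejected input row, with its (1-based, data) row index and reason."""

    row_index: int
    subject_id: str
    reason: str


@dataclass
class CohortTable:
    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[str, int] = {}
        for rec in self.records:
            seen[rec.subject_id] = seen.get(rec.subject_id, 0) + 1
        dupes = sorted(k for k, v in seen.items() if v > 1)
        if dupes:
            raise CohortError(f"duplicate subject_id values: {dupes}")
        states = {rec.unit_state for rec in self.records}
        if len(states) > 1:
            raise CohortError(f"mixed unit states in one table: {sorted(states)}")

    @property
    def unit_state(self) -> str | None:
        return self.records[0].unit_state if self.records else None

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, keep: Iterable[SubjectRecord]) -> "CohortTable":
        return CohortTable(records=list(keep), provenance=self.provenance)

    def counts_by_group(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.group] = out.get(rec.group, 0) + 1
        return out


def load_schema_config(path: str | Path) -> dict[str, str]:
    """Read a canonical-name -> file-column-name mapping (YAML or JSON)."""
    text = Path(path).read_text(encoding="utf-8")
    mapping = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(mapping, dict):
        raise CohortError(f"schema config {path} must be a flat mapping")
    unknown = set(mapping) - set(COLUMNS)
    if unknown:
        raise CohortError(f"schema config maps unknown canonical columns: {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


def _fmt(x: float | int | None) -> str:
    if x is None:
        return MISSING_SENTINEL
    return repr(float(x)) if isinstance(x, float) else str(x)


def _parse_float(cell: str, what: str, *, positive: bool = False) -> float | None:
    if cell == MISSING_SENTINEL:
        return None
    try:
        v = float(cell)
    except ValueError:
        raise ValueError(f"{what}: cannot parse {cell!r} as a number") from None
    if positive and v <= 0:
        raise ValueError(f"{what}: must be positive, got {v}")
    return v


def _parse_toxin(cell: str) -> ToxinEntry:
    cell = cell.strip()
    if cell == MISSING_SENTINEL:
        return ToxinEntry(None, FLAG_MISSING)
    if cell == LOQ_SENTINEL:
        return ToxinEntry(None, FLAG_BELOW_LOQ)
    v = float(cell)
    if v < 0:
        raise ValueError(f"toxin value must be non-negative, got {v}")
    return ToxinEntry(v, FLAG_OK)


def read_cohort(
    path: str | Path,
    schema_config: Mapping[str, str] | str | Path | None = None,
) -> CohortTable:
    """Read and validate a tidy cohort CSV.

    Rows that fail type coercion or range rules are rejected individually
    and reported in ``table.diagnostics`` (rejection is total: every input
    row is either a record or a diagnostic).  Structural problems — a
    missing required column, duplicate subject ids among accepted rows —
    are fatal.
    """
    path = Path(path)
    if schema_config is None:
        colmap = {c: c for c in COLUMNS}
    elif isinstance(schema_config, (str, Path)):
        loaded = load_schema_config(schema_config)
        colmap = {c: loaded.get(c, c) for c in COLUMNS}
    else:
        colmap = {c: schema_config.get(c, c) for c in COLUMNS}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        absent = [colmap[c] for c in COLUMNS if colmap[c] not in header]
        if absent:
            raise CohortError(f"{path}: required column(s) missing: {absent}")

        records: list[SubjectRecord] = []
        diagnostics: list[RowDiagnostic] = []
        for i, row in enumerate(reader, start=1):
            sid = (row.get(colmap["subject_id"]) or "").strip()
            try:
                records.append(_parse_row(row, colmap, sid))
            except (ValueError, CohortError) as exc:
                diagnostics.append(RowDiagnostic(i, sid, str(exc)))

    table = CohortTable(records=records, provenance=str(path))
    table.diagnostics = diagnostics
    return table


def _parse_row(row: Mapping[str, str], colmap: Mapping[str, str], sid: str) -> SubjectRecord:
    def cell(name: str) -> str:
        return (row.get(colmap[name]) or "").strip()

    if not sid:
        raise ValueError("empty subject_id")
    group = cell("group").lower()
    sex = cell("sex").lower() or "unknown"
    age = _parse_float(cell("age_years"), "age_years")
    if age is None:
        raise ValueError("age_years is required")
    bsc_cell = cell("bsc_type")
    if bsc_cell == MISSING_SENTINEL:
        bsc: int | None = None
    else:
        try:
            bsc = int(bsc_cell)
        except ValueError:
            raise ValueError(f"bsc_type: non-integer value {bsc_cell!r}") from None
        if bsc not in range(1, 8):
            raise ValueError(f"bsc_type: {bsc} outside 1..7")
    creat = _parse_float(cell("creatinine"), "creatinine", positive=True)
    unit_state = cell("unit_state")
    toxins = {a: _parse_toxin(cell(a)) for a in ANALYTES}
    return SubjectRecord(
        subject_id=sid,
        group=group,
        sex=sex,
        age_years=age,
        bsc_type=bsc,
        creatinine=creat,
        toxins=toxins,
        unit_state=unit_state,
    )


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    """Write a validated table in the canonical CSV dialect (UTF-8, header).

    Floats are written with ``repr`` so that ``read_cohort(write_cohort(t))``
    reproduces ``t`` field-for-field.
    """
    table.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in table.records:
            row = [
                rec.subject_id,
                rec.group,
                rec.sex,
                _fmt(rec.age_years),
                _fmt(rec.bsc_type),
                _fmt(rec.creatinine),
                rec.unit_state,
            ]
            for a in ANALYTES:
                entry = rec.toxins[a]
                if entry.flag == FLAG_MISSING:
                    row.append(MISSING_SENTINEL)
                elif entry.flag == FLAG_BELOW_LOQ:
                    row.append(LOQ_SENTINEL)
                else:
                    row.append(_fmt(entry.value))
            writer.writerow(row)
    return path


def records_equal(a: SubjectRecord, b: SubjectRecord) -> bool:
    """Field-for-field equality ignoring derived bookkeeping."""
    return replace(a, normalization_excluded=False) == replace(b, normalization_excluded=False)
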