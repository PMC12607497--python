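"""Creatinine normalization and Bristol-stool phenotype stratification.

Urinary analyte concentrations vary with hydration; dividing by urinary
creatinine (mmol/L) converts µmol/L to µmol/mmol creatinine and removes
dilution.  Stool phenotype follows the Bristol Stool Chart: types 1–2 are
hard stools (slow transit), 3–5 normal, 6–7 loose (fast transit).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

from .cohort_io import (
    ANALYTES,
    FLAG_OK,
    NORMALIZED,
    CohortTable,
    SubjectRecord,
    ToxinEntry,
)

HARD = "hard"
NORMAL = "normal"
LOOSE = "loose"

#: the three phenotype categories partition BSC types 1..7
BSC_CATEGORIES: dict[str, frozenset[int]] = {
    HARD: frozenset({1, 2}),
    NORMAL: frozenset({3, 4, 5}),
    LOOSE: frozenset({6, 7}),
}


def normalize_to_creatinine(value: float, creatinine: float) -> float:
    """µmol/L analyte over mmol/L creatinine -> µmol/mmol creatinine."""
    if creatinine is None or creatinine <= 0:
        raise ValueError(f"creatinine must be positive, got {creatinine}")
    if value < 0:
        raise ValueError(f"analyte value must be non-negative, got {value}")
    return value / creatinine


def assign_bsc_category(bsc_type: int | None) -> str | None:
    """Map a BSC type to hard/normal/loose; None when type is missing/out of range."""
    if bsc_type is None:
        return None
    for label, members in BSC_CATEGORIES.items():
        if bsc_type in members:
            return label
    return None


def normalize_record(record: SubjectRecord) -> SubjectRecord:
    """Flip one record from raw to creatinine-normalized units.

    A record already in normalized units passes through unchanged (checked
    no-op).  A raw record without a usable creatinine is *flagged*
    ``normalization_excluded`` — it stays in the table but its toxin values
    cannot enter normalized analyses.
    """
    if record.unit_state == NORMALIZED:
        return record
    if record.creatinine is None or record.creatinine <= 0:
        return replace(record, normalization_excluded=True)
    toxins = {}
    for analyte in ANALYTES:
        entry = record.toxins[analyte]
        if entry.flag == FLAG_OK:
            toxins[analyte] = ToxinEntry(
                normalize_to_creatinine(entry.value, record.creatinine), FLAG_OK
            )
        else:
            toxins[analyte] = entry
    return replace(record, toxins=toxins, unit_state=NORMALIZED)


def normalize_cohort(table: CohortTable) -> CohortTable:
    """Normalize every record; exclusions are flagged, never dropped."""
    if table.unit_state in (None, NORMALIZED):
        return table
    out = CohortTable(
        records=[normalize_record(r) for r in table.records],
        provenance=table.provenance,
    )
    out.diagnostics = list(table.diagnostics)
    return out


def stratify(table: CohortTable) -> dict[str, list[SubjectRecord]]:
    """Partition records into analysis strata.

    Returns the five study strata: ``control``, ``asd_all`` plus the three
    ASD stool-phenotype subgroups ``asd_hard`` / ``asd_normal`` /
    ``asd_loose``.  ASD subjects with a missing BSC type belong to
    ``asd_all`` but to no subgroup.
    """
    strata: dict[str, list[SubjectRecord]] = {
        "control": [],
        "asd_all": [],
        "asd_hard": [],
        "asd_normal": [],
        "asd_loose": [],
    }
    for rec in table.records:
        if rec.group == "control":
            strata["control"].append(rec)
            continue
        strata["asd_all"].append(rec)
        category = assign_bsc_category(rec.bsc_type)
        if category is not None:
            strata[f"asd_{category}"].append(rec)
    return strata


def eligible_for_normalized_analysis(records: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    return [r for r in records if not r.normalization_excluded]
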