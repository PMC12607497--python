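"""Component toxin ratios and the composite MIGD/OGI index.

The Metabolic Index of Gut Dysfunction (also called the Osredkar-Godnov
Index) condenses four creatinine-normalized urinary analytes into one
dimensionless number::

    MIGD = (PCS/TMAO × 100) / (IS/ADMA)

PCS/TMAO tracks phenolic (tyrosine-derived) fermentation against
methylamine metabolism; IS/ADMA tracks indolic (tryptophan-derived)
output against host detoxification load.  High values mean phenolic
dominance with suppressed indolic clearance — the slow-transit profile;
low values the converse.  SDMA is carried through the data model as a
renal-context marker but never enters the index.

Two precision modes are exposed and always labelled on results:

``full``
    unrounded arithmetic; use for statistics.
``report_1dp``
    each component ratio is rounded half-up to one decimal *before* the
    index is formed, and the index is rounded to one decimal; this is the
    convention that reproduces published group-level report tables.

The index is a ratio of ratios, so it is invariant to rescaling all four
analytes by a common factor — in particular to the subject's creatinine.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Iterable, Mapping

from .cohort_io import FLAG_OK, SubjectRecord

#: the four analytes entering the index (SDMA deliberately absent)
INDEX_ANALYTES = ("PCS", "TMAO", "IS", "ADMA")

FULL = "full"
REPORT_1DP = "report_1dp"

GROUP_LEVEL = "group_level"
INDIVIDUAL_LEVEL = "individual_level"

#: values at or below this (µmol/mmol creatinine) count as a near-zero denominator
DEFAULT_DENOMINATOR_FLOOR = 1e-6

# interpretation bands: left-closed partition of [0, inf)
BAND_LOW = "low"
BAND_MILD_MODERATE = "mild_moderate"
BAND_MARKED = "marked"
BAND_HIGH = "high"
BAND_SEVERE = "severe"

#: (lower edge, band label); upper edge is the next entry's lower edge
BAND_EDGES = (
    (0.0, BAND_LOW),
    (50.0, BAND_MILD_MODERATE),
    (150.0, BAND_MARKED),
    (300.0, BAND_HIGH),
    (500.0, BAND_SEVERE),
)

BAND_PHRASES = {
    BAND_LOW: "Low metabolic disruption or compensatory indole pathway activity",
    BAND_MILD_MODERATE: "Mild to moderate metabolic imbalance",
    BAND_MARKED: "Marked microbial–host metabolic disturbance",
    BAND_HIGH: "High dysfunction—skewed fermentation and impaired detoxification",
    BAND_SEVERE: "Severe imbalance—indicates high systemic fermentation burden",
}

REASON_NONE = "none"
REASON_NEAR_ZERO = "near_zero_denominator"
REASON_MISSING = "missing_analyte"


class RatioError(ValueError):
    """A component ratio cannot be formed; carries the exclusion reason."""

    reason = REASON_NONE


class NearZeroDenominator(RatioError):
    reason = REASON_NEAR_ZERO


class MissingAnalyte(RatioError):
    reason = REASON_MISSING


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (clinical reporting convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


ToxinPanel = Mapping[str, float | None]
"""Analyte -> value in µmol/mmol creatinine; None marks missing/below-LOQ."""


def panel_from_record(record: SubjectRecord) -> dict[str, float | None]:
    return {
        a: (record.toxins[a].value if record.toxins[a].flag == FLAG_OK else None)
        for a in record.toxins
    }


@dataclass(frozen=True)
class RatioSet:
    pcs_tmao: float
    is_adma: float
    precision_mode: str = FULL


@dataclass(frozen=True)
class MigdResult:
    value: float | None
    mode: str
    precision_mode: str
    band: str | None
    excluded: bool = False
    exclusion_reason: str = REASON_NONE
    n: int | None = None  # records behind a group-level result

    @property
    def band_phrase(self) -> str | None:
        return BAND_PHRASES.get(self.band) if self.band else None


def compute_ratios(
    panel: ToxinPanel,
    precision_mode: str = FULL,
    floor: float = DEFAULT_DENOMINATOR_FLOOR,
) -> RatioSet:
    """Form PCS/TMAO and IS/ADMA from one panel.

    Raises :class:`MissingAnalyte` if any of the four index analytes is
    absent, :class:`NearZeroDenominator` if TMAO or ADMA is at/below the
    floor.
    """
    missing = [a for a in INDEX_ANALYTES if panel.get(a) is None]
    if missing:
        raise MissingAnalyte(f"index analytes unavailable: {missing}")
    pcs, tmao, is_, adma = (panel[a] for a in INDEX_ANALYTES)
    if tmao <= floor or adma <= floor:
        raise NearZeroDenominator(
            f"denominator at/below floor {floor}: TMAO={tmao}, ADMA={adma}"
        )
    pcs_tmao = pcs / tmao
    is_adma = is_ / adma
    if precision_mode == REPORT_1DP:
        pcs_tmao = round_half_up(pcs_tmao, 1)
        is_adma = round_half_up(is_adma, 1)
    return RatioSet(pcs_tmao=pcs_tmao, is_adma=is_adma, precision_mode=precision_mode)


def compute_migd(
    ratios: RatioSet,
    mode: str = GROUP_LEVEL,
    floor: float = DEFAULT_DENOMINATOR_FLOOR,
) -> MigdResult:
    """(PCS/TMAO × 100) / (IS/ADMA), honouring the ratio set's precision mode."""
    if ratios.is_adma <= floor:
        raise NearZeroDenominator(f"IS/ADMA at/below floor: {ratios.is_adma}")
    value = ratios.pcs_tmao * 100.0 / ratios.is_adma
    if ratios.precision_mode == REPORT_1DP:
        value = round_half_up(value, 1)
    return MigdResult(
        value=value,
        mode=mode,
        precision_mode=ratios.precision_mode,
        band=classify_migd(value),
    )


def classify_migd(value: float) -> str:
    """Interpretation band for an index value; left-closed partition of [0, ∞)."""
    if value < 0:
        raise ValueError(f"index value must be non-negative, got {value}")
    band = BAND_EDGES[0][1]
    for lower, label in BAND_EDGES:
        if value >= lower:
            band = label
    return band


def individual_level_migd(
    panel: ToxinPanel,
    precision_mode: str = FULL,
    floor: float = DEFAULT_DENOMINATOR_FLOOR,
) -> MigdResult:
    """Per-subject index; exclusion is a value, not a failure."""
    try:
        ratios = compute_ratios(panel, precision_mode, floor)
        result = compute_migd(ratios, mode=INDIVIDUAL_LEVEL, floor=floor)
    except RatioError as exc:
        return MigdResult(
            value=None,
            mode=INDIVIDUAL_LEVEL,
            precision_mode=precision_mode,
            band=None,
            excluded=True,
            exclusion_reason=exc.reason,
        )
    return result


def group_level_migd(
    panels: Iterable[ToxinPanel],
    precision_mode: str = FULL,
    floor: float = DEFAULT_DENOMINATOR_FLOOR,
) -> MigdResult:
    """Index of the median panel: per-analyte medians, then ratios, then index.

    This is the convention behind published group tables (medians of each
    analyte within the stratum feed the formula once).
    """
    panels = list(panels)
    eligible = [
        p for p in panels if all(p.get(a) is not None for a in INDEX_ANALYTES)
    ]
    if not eligible:
        raise MissingAnalyte("no record with all four index analytes present")
    median_panel = {
        a: median(p[a] for p in eligible) for a in INDEX_ANALYTES
    }
    ratios = compute_ratios(median_panel, precision_mode, floor)
    result = compute_migd(ratios, mode=GROUP_LEVEL, floor=floor)
    return MigdResult(
        value=result.value,
        mode=GROUP_LEVEL,
        precision_mode=precision_mode,
        band=result.band,
        n=len(eligible),
    )
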