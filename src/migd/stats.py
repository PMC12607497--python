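"""Subgroup summaries, non-parametric comparisons, FDR control, power.

All group comparisons use the tie-corrected Kruskal–Wallis test (the data
are right-skewed and non-normal), with the chi-square reference on k−1
degrees of freedom; two-group contrasts are Kruskal–Wallis with k = 2.
Families of p values are adjusted with the Benjamini–Hochberg step-up
procedure.  The sample-size helper inverts the noncentral-t power
function of the two-sided two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from .cohort_io import ANALYTES, CohortTable, SubjectRecord
from .core import (
    DEFAULT_DENOMINATOR_FLOOR,
    FULL,
    individual_level_migd,
    panel_from_record,
)
from .normalize import stratify

KRUSKAL_WALLIS = "kruskal_wallis"
BENJAMINI_HOCHBERG = "benjamini_hochberg"

#: non-control strata in table order
ASD_SUBGROUPS = ("asd_hard", "asd_loose", "asd_normal")


@dataclass(frozen=True)
class SubgroupSummary:
    group_key: str
    analyte_or_index: str
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    method: str = KRUSKAL_WALLIS
    adjustment: str = BENJAMINI_HOCHBERG
    degenerate: bool = False


@dataclass
class ComparisonConfig:
    """Knobs for the comparison pipeline.

    ``bh_family`` — ``per_analyte`` adjusts each analyte's contrasts as one
    family (the published per-analyte row layout); ``global`` pools all.
    ``omnibus_scope`` — ``three_subgroup`` tests across the three ASD stool
    subgroups; ``four_group`` adds the controls.
    """

    alpha: float = 0.05
    bh_family: str = "per_analyte"
    omnibus_scope: str = "three_subgroup"
    denominator_floor: float = DEFAULT_DENOMINATOR_FLOOR
    analytes: Sequence[str] = field(default_factory=lambda: list(ANALYTES) + ["MIGD"])


def median_quartiles(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quantiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_quartiles needs at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in input")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def kruskal_wallis(*groups: Sequence[float], comparison: str = "") -> TestResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p on k−1 df.

    When every pooled value is identical the statistic is 0 by convention,
    p = 1, and the result is flagged degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(comparison, 0.0, 1.0, degenerate=True)
    h, p = sps.kruskal(*arrays)
    return TestResult(comparison, float(h), float(p))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p values, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adjusted]


def power_two_sample_t(n_per_group: int, effect_size_d: float, alpha: float) -> float:
    """Power of the two-sided two-sample t test (equal n, noncentral t)."""
    return float(
        TTestIndPower().power(
            effect_size=effect_size_d, nobs1=n_per_group, alpha=alpha,
            ratio=1.0, alternative="two-sided",
        )
    )


def sample_size_two_group(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Smallest n per group reaching the requested power at effect d."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    approx = TTestIndPower().solve_power(
        effect_size=effect_size_d, alpha=alpha, power=power,
        ratio=1.0, alternative="two-sided",
    )
    n = max(2, int(np.floor(approx)) - 1)
    while power_two_sample_t(n, effect_size_d, alpha) < power:
        n += 1
    return n


def _values_for(records: Iterable[SubjectRecord], analyte: str, floor: float) -> list[float]:
    """Analysable values of one analyte (or the index) in a stratum."""
    out: list[float] = []
    for rec in records:
        if rec.normalization_excluded:
            continue
        if analyte == "MIGD":
            res = individual_level_migd(panel_from_record(rec), FULL, floor)
            if not res.excluded:
                out.append(res.value)
        else:
            v = rec.toxin_value(analyte)
            if v is not None:
                out.append(v)
    return out


def summarize_subgroups(
    table: CohortTable,
    analytes: Sequence[str] | None = None,
    floor: float = DEFAULT_DENOMINATOR_FLOOR,
) -> list[SubgroupSummary]:
    """Median (Q1, Q3) per (stratum × analyte/index)."""
    analytes = list(analytes) if analytes is not None else list(ANALYTES) + ["MIGD"]
    strata = stratify(table)
    summaries: list[SubgroupSummary] = []
    for key, records in strata.items():
        for analyte in analytes:
            vals = _values_for(records, analyte, floor)
            if not vals:
                continue
            med, q1, q3 = median_quartiles(vals)
            summaries.append(SubgroupSummary(key, analyte, len(vals), med, q1, q3))
    return summaries


def run_comparisons(
    table: CohortTable,
    config: ComparisonConfig | None = None,
) -> tuple[list[TestResult], list[SubgroupSummary], list[str]]:
    """The study's comparison scheme over a normalized, stratified cohort.

    Per analyte (and the individual-level index): control vs ASD(all),
    control vs each stool subgroup, and the across-subgroup omnibus
    ("p TOT"), with BH adjustment applied within the configured family.
    Returns (tests, summaries, skipped-comparison diagnostics).
    """
    config = config or ComparisonConfig()
    strata = stratify(table)
    skipped: list[str] = []
    tests: list[TestResult] = []
    families: dict[str, list[int]] = {}

    for analyte in config.analytes:
        values = {
            key: _values_for(records, analyte, config.denominator_floor)
            for key, records in strata.items()
        }
        contrasts: list[tuple[str, list[list[float]]]] = [
            (f"{analyte}: control vs asd_all", [values["control"], values["asd_all"]]),
        ]
        for sub in ASD_SUBGROUPS:
            contrasts.append(
                (f"{analyte}: control vs {sub}", [values["control"], values[sub]])
            )
        omnibus_groups = [values[s] for s in ASD_SUBGROUPS]
        if config.omnibus_scope == "four_group":
            omnibus_groups = [values["control"]] + omnibus_groups
        contrasts.append((f"{analyte}: omnibus ({config.omnibus_scope})", omnibus_groups))

        idx_this_analyte: list[int] = []
        for name, groups in contrasts:
            if any(len(g) == 0 for g in groups):
                skipped.append(f"{name}: skipped, empty group")
                continue
            result = kruskal_wallis(*groups, comparison=name)
            idx_this_analyte.append(len(tests))
            tests.append(result)
        families[analyte] = idx_this_analyte

    if config.bh_family == "global":
        family_indices = [list(range(len(tests)))]
    else:
        family_indices = [idx for idx in families.values() if idx]
    for idx in family_indices:
        adjusted = bh_adjust([tests[i].p_raw for i in idx])
        for i, p_adj in zip(idx, adjusted):
            t = tests[i]
            tests[i] = TestResult(
                t.comparison, t.statistic, t.p_raw, p_adj,
                t.method, t.adjustment, t.degenerate,
            )

    summaries = summarize_subgroups(table, config.analytes, config.denominator_floor)
    return tests, summaries, skipped
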