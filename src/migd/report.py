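"""Build the analysis tables: per-analyte summaries, per-subject index
summaries, group-level ratio/index rows with interpretation bands, and
the comparison table — plus a machine-readable run summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from statistics import median

import pandas as pd

from . import __version__
from .cohort_io import ANALYTES, CohortTable
from .core import (
    DEFAULT_DENOMINATOR_FLOOR,
    FULL,
    GROUP_LEVEL,
    INDEX_ANALYTES,
    REPORT_1DP,
    MissingAnalyte,
    NearZeroDenominator,
    compute_migd,
    compute_ratios,
    group_level_migd,
    individual_level_migd,
    panel_from_record,
    RatioSet,
)
from .normalize import stratify
from .stats import ComparisonConfig, median_quartiles, run_comparisons
from .synth import load_reference_tables

#: stratum display order in every table
STRATA_ORDER = ("control", "asd_all", "asd_hard", "asd_loose", "asd_normal")


def build_table1(table: CohortTable) -> pd.DataFrame:
    """Per-analyte Median (Q1, Q3) by stratum — tidy layout."""
    strata = stratify(table)
    rows = []
    for key in STRATA_ORDER:
        records = [r for r in strata[key] if not r.normalization_excluded]
        for analyte in ANALYTES:
            vals = [v for r in records if (v := r.toxin_value(analyte)) is not None]
            if vals:
                med, q1, q3 = median_quartiles(vals)
            else:
                med = q1 = q3 = float("nan")
            rows.append(
                {"stratum": key, "analyte": analyte, "n": len(vals),
                 "median": med, "q1": q1, "q3": q3}
            )
    return pd.DataFrame(rows)


def build_table2(
    table: CohortTable, floor: float = DEFAULT_DENOMINATOR_FLOOR
) -> pd.DataFrame:
    """Individual-level index Median (Q1, Q3) per stratum with exclusion counts."""
    strata = stratify(table)
    rows = []
    for key in STRATA_ORDER:
        values, n_floor, n_missing = [], 0, 0
        for rec in strata[key]:
            if rec.normalization_excluded:
                n_missing += 1
                continue
            res = individual_level_migd(panel_from_record(rec), FULL, floor)
            if res.excluded:
                if res.exclusion_reason == "near_zero_denominator":
                    n_floor += 1
                else:
                    n_missing += 1
            else:
                values.append(res.value)
        if values:
            med, q1, q3 = median_quartiles(values)
        else:
            med = q1 = q3 = float("nan")
        rows.append(
            {"stratum": key, "index": "MIGD", "n": len(values),
             "median": med, "q1": q1, "q3": q3,
             "excluded_near_zero_denominator": n_floor,
             "excluded_missing_analyte": n_missing}
        )
    return pd.DataFrame(rows)


def build_table3(
    table: CohortTable, floor: float = DEFAULT_DENOMINATOR_FLOOR
) -> pd.DataFrame:
    """Group-level component ratios and index, report precision, with bands."""
    strata = stratify(table)
    rows = []
    for key in STRATA_ORDER:
        records = [r for r in strata[key] if not r.normalization_excluded]
        panels = [panel_from_record(r) for r in records]
        try:
            res = group_level_migd(panels, REPORT_1DP, floor)
            ratios = _group_ratios(panels, floor)
            rows.append(
                {"stratum": key, "n": res.n,
                 "pcs_tmao": ratios.pcs_tmao, "is_adma": ratios.is_adma,
                 "migd": res.value, "band": res.band,
                 "interpretation": res.band_phrase}
            )
        except (MissingAnalyte, NearZeroDenominator) as exc:
            rows.append(
                {"stratum": key, "n": 0, "pcs_tmao": float("nan"),
                 "is_adma": float("nan"), "migd": float("nan"),
                 "band": "unclassified", "interpretation": str(exc)}
            )
    return pd.DataFrame(rows)


def _group_ratios(panels, floor) -> RatioSet:
    eligible = [p for p in panels if all(p.get(a) is not None for a in INDEX_ANALYTES)]
    median_panel = {a: median(p[a] for p in eligible) for a in INDEX_ANALYTES}
    return compute_ratios(median_panel, REPORT_1DP, floor)


def reference_table3() -> pd.DataFrame:
    """Group-level ratios/index recomputed from the published stratum medians.

    Desk calculation in report precision — no cohort needed.  The control
    row's stratum medians are not published per stool category, so it is
    reproduced from the published control component ratios instead.
    """
    ref = load_reference_tables()
    rows = []
    for key in ("asd_hard", "asd_loose", "asd_normal"):
        med = {a: ref["toxin_summaries"][key][a][0] for a in ANALYTES}
        ratios = compute_ratios(med, REPORT_1DP)
        res = compute_migd(ratios, mode=GROUP_LEVEL)
        rows.append(
            {"stratum": key, "pcs_tmao": ratios.pcs_tmao, "is_adma": ratios.is_adma,
             "migd": res.value, "band": res.band, "interpretation": res.band_phrase}
        )
    pub = ref["published_group_ratios"]["control"]
    ratios = RatioSet(pub["pcs_tmao"], pub["is_adma"], REPORT_1DP)
    res = compute_migd(ratios, mode=GROUP_LEVEL)
    rows.insert(
        0,
        {"stratum": "control", "pcs_tmao": ratios.pcs_tmao, "is_adma": ratios.is_adma,
         "migd": res.value, "band": res.band, "interpretation": res.band_phrase},
    )
    return pd.DataFrame(rows)


def analyze_cohort(
    table: CohortTable,
    output_dir: str | Path,
    config: ComparisonConfig | None = None,
) -> dict:
    """Run the full analysis and write table1..3, tests.csv, summary.json."""
    config = config or ComparisonConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t1 = build_table1(table)
    t2 = build_table2(table, config.denominator_floor)
    t3 = build_table3(table, config.denominator_floor)
    tests, summaries, skipped = run_comparisons(table, config)
    tests_df = pd.DataFrame([asdict(t) for t in tests])

    t1.to_csv(out / "table1.csv", index=False)
    t2.to_csv(out / "table2.csv", index=False)
    t3.to_csv(out / "table3.csv", index=False)
    tests_df.to_csv(out / "tests.csv", index=False)

    counts = table.counts_by_group()
    config_blob = json.dumps(asdict(config), sort_keys=True, default=list)
    summary = {
        "version": __version__,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        "provenance": table.provenance,
        "n_subjects": len(table),
        "n_by_group": counts,
        "n_rejected_rows": len(table.diagnostics),
        "stage_counts": {
            "read": len(table) + len(table.diagnostics),
            "validated": len(table),
            "migd_eligible": int(t2["n"].sum()),
            "tested": len(tests),
            "skipped_comparisons": len(skipped),
        },
        "skipped": skipped,
        "group_level_migd": {
            row["stratum"]: row["migd"] for _, row in t3.iterrows()
        },
    }
    with (out / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
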