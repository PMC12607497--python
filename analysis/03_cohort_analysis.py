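#!/usr/bin/env python
"""Full pipeline on the simulated cohort from 01: per-analyte summaries,
individual-level index summaries with exclusion accounting, group-level
ratio/index rows with bands, and Kruskal–Wallis comparisons with
Benjamini–Hochberg adjustment (per-analyte families).
"""

from pathlib import Path

import pandas as pd

from migd.cohort_io import read_cohort
from migd.report import analyze_cohort

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort.csv"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    if not COHORT.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    table = read_cohort(COHORT)
    summary = analyze_cohort(table, OUT)
    print(f"analyzed {summary['n_subjects']} subjects; outputs in {OUT}")
    t3 = pd.read_csv(OUT / "table3.csv")
    print("\ngroup-level index (report precision):")
    print(t3[["stratum", "n", "pcs_tmao", "is_adma", "migd", "band"]].to_string(index=False))
    tests = pd.read_csv(OUT / "tests.csv")
    migd_rows = tests[tests["comparison"].str.startswith("MIGD")]
    print("\nindex comparisons (raw / BH-adjusted p):")
    print(migd_rows[["comparison", "statistic", "p_raw", "p_adjusted"]].to_string(index=False))
    print(
        "\nAt the study's stratum sizes the simulated contrasts are, as in the "
        "source cohort, directional rather than significant after FDR control."
    )


if __name__ == "__main__":
    main()
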