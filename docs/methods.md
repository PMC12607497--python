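# Methods

## The composite index

For each subject (or stratum) with creatinine-normalized urinary
concentrations (µmol/mmol creatinine) of p-cresyl sulfate (PCS),
trimethylamine N-oxide (TMAO), indoxyl sulfate (IS) and asymmetric
dimethylarginine (ADMA), the Metabolic Index of Gut Dysfunction is

    MIGD = (PCS/TMAO × 100) / (IS/ADMA).

The ×100 factor is cosmetic (readability of the scale). The index is
dimensionless, strictly increasing in PCS and ADMA and strictly decreasing
in TMAO and IS, and invariant to rescaling all four analytes by a common
factor — hence invariant to urinary dilution and to the creatinine
denominator. SDMA is measured and summarized as a renal-clearance context
marker but deliberately excluded from the index.

Two **calculation modes** exist and are always labelled on results:

- *group-level*: per-analyte medians over a stratum feed the formula once
  (the convention behind published group tables);
- *individual-level*: the formula per subject, used for statistics;
  subjects with TMAO or ADMA at or below the denominator floor are excluded
  with reason `near_zero_denominator`, subjects missing any of the four
  analytes with `missing_analyte`. Exclusions are values, not errors, and
  are counted in every summary.

Two **precision modes** exist because published group tables are consistent
with rounding each component ratio half-up to one decimal *before* forming
the index (e.g. 19.6 × 100 / 3.5 = 560.0) whereas unrounded medians give
≈ 554.7: `report_1dp` reproduces the published tables; `full` is used for
statistics. Rounding is decimal half-up (clinical convention), not
banker's. The source abstract quotes stratum medians (555.3, 109.8) that
match neither convention; whatever intermediate precision produced them is
not recoverable, so they are not asserted anywhere.

**Denominator floor.** "Near-zero" is implemented as ≤ 1e-6 µmol/mmol
creatinine by default, configurable; the published description gives no
threshold, and at this floor no realistic panel is excluded spuriously
while exact zeros are.

**Interpretation bands.** The published ranges overlap (">300" and ">500";
"50–150" and "150–300" share endpoints). They are implemented as the
left-closed partition [0,50) low, [50,150) mild-moderate, [150,300) marked,
[300,500) high, [500,∞) severe — ">500" is read as the upper sub-band of
">300", and each shared endpoint belongs to the upper band. This is a
forced disambiguation; report output carries the original phrasing.

## Cohort model and stratification

One row per subject: id, group (control/ASD), sex, age, Bristol Stool
Chart type (integer 1–7, possibly missing), urinary creatinine (mmol/L),
five analytes with per-analyte flags (`ok`, `below_loq`, `missing`) and an
explicit unit state shared by the whole table. Missing cells are written
as the empty string and below-LOQ cells as `<LOQ`, so write → read is the
identity on validated tables; floats are serialized with `repr` for exact
numeric round-trip. Rows failing coercion are rejected individually with
row-indexed diagnostics (rejection is total: accepted + rejected = read).

Raw tables (µmol/L) are normalized by dividing each analyte by creatinine;
already-normalized tables pass through as a checked no-op. Records without
a usable creatinine are flagged `normalization_excluded`, never dropped.

Stool phenotypes: BSC 1–2 hard, 3–5 normal, 6–7 loose — a total partition
of {1..7}. ASD subjects with a missing BSC type belong to the all-ASD
stratum but to no subgroup; stratification and normalization commute.

## Statistics

All group contrasts use the tie-corrected Kruskal–Wallis test with the
chi-square reference on k−1 degrees of freedom (the analytes are
right-skewed and non-normal); two-group contrasts are Kruskal–Wallis with
k = 2, equivalent to a two-sided rank test up to tie convention. If every
pooled value is identical the statistic is 0 and p = 1 by convention,
flagged degenerate. The comparison scheme per analyte (and the
individual-level index) is: control vs ASD(all), control vs each stool
subgroup, and an across-subgroup omnibus — by default over the three ASD
subgroups, optionally including controls as a fourth group (the published
tables do not say which; both are exposed).

Benjamini–Hochberg step-up adjustment is applied within a family; the
default family is one analyte's set of contrasts (matching the per-analyte
row layout of the published tables), with a switch for one global family.
Adjusted values never fall below raw ones and preserve their ranking.

Quartile summaries use linear-interpolation quantiles at 0.25/0.5/0.75 —
the default of mainstream statistics environments, including the one the
source analysis was run in; quartile conventions differ and none is stated,
so this is a documented choice.

`sample_size_two_group(d, α, power)` returns the smallest integer n per
group for which the two-sided two-sample t test at equal group sizes
reaches the requested power, using the noncentral-t power function
(statsmodels' implementation, cross-checked in the tests against a direct
noncentral-t computation in scipy). With d = 0.5, α = 0.05, power = 0.80
it returns 64 per group; "moderate effect" is interpreted as Cohen's
d = 0.5, the unique reading that yields the published 64/group.

## Synthetic cohort generator

No subject-level data are deposited, so the pipeline is exercised on
seeded synthetic cohorts that emulate the published summary structure:

- **Stratum sizes** 71 controls and 97 ASD (28 hard / 8 loose / 61 normal),
  sex fractions and truncated-normal age models (mean, SD, min, max) per
  stratum, all transcribed into `src/migd/data/reference_targets.yaml`.
- **Analytes**: each (stratum, analyte) is log-normal with
  `mu = ln(median)` and `sigma = ln(Q3/Q1)/(2·0.674490)`, fitted to that
  stratum's published median/(Q1, Q3). The fit reproduces the median and
  the quartile *ratio* exactly; a two-parameter family cannot also match
  both quartiles individually. Log-normality is a modelling choice
  motivated by positivity and the pronounced right skew of every published
  summary (Q3 − median > median − Q1); the source analysis reports
  non-normality but no family.
- **BSC types** are uniform within each stratum's member set. Control
  stool-subgroup summaries are not published, so all control strata share
  the all-control targets and controls default to the normal-stool
  category (the scale on which the published control ratios are labelled)
  — a documented limitation.
- **Creatinine** is filled with plausible pediatric first-morning values
  (log-normal, median 8 mmol/L, log-sd 0.6); it is plumbing only, since
  cohorts are generated directly in normalized units and the index is
  creatinine-invariant.
- Analytes are sampled independently within subject (no inter-analyte
  correlations are published); a log-scale correlation matrix hook exists
  for sensitivity studies, default identity. Optional below-LOQ censoring
  thresholds and a missingness rate are applied last.
- Identical spec + seed ⇒ byte-identical cohorts.

What passing tests show — and do not show — about real data: the generator
reproduces stratum sizes, demographics, marginal medians and quartile
ratios, but not inter-analyte correlation (e.g. PCS–IS co-production),
batch or diet effects, within-subject day-to-day variability, or the true
joint distribution of the index; cohort-level index medians emerge from
the marginals and need not match the published individual-level index
summaries. Published subject-level medians and p values are therefore not
reproduction targets; calibration-recovery and property-based checks stand
in for them.

## Problem sizes and numerical checks used by the test suite

- Calibration recovery: n = 5000 per stratum, every stratum/analyte sample
  median within 5% of its target; the hard-stool group-level index in
  report mode within 5% of 560.0 (the propagated tolerance of 5%-accurate
  medians; its Monte-Carlo SE at this n is ≈ 2%). One stratum — loose-stool
  TMAO, whose published quartiles imply log-sd ≈ 3.4 — has a sample-median
  SE of ≈ 6% at this n, so the 5% bound is intrinsically tight for that
  cell; the suite runs it at a fixed seed.
- Distribution-fit recovery at n = 10⁶: sample median within 1%, Q3/Q1
  within 2%.
- Kruskal–Wallis H is checked against an independent rank-formula oracle
  (with tie correction) on every 3|3 split of six observations and on tied
  datasets; type-I error is simulated at 1000 reps (single test) and 500
  reps (full pipeline, 20/stratum) against the 95% binomial envelope of
  α = 0.05.
- Index invariances (creatinine/scale invariance, sign-correct
  monotonicity) are exercised on 10,000 random panels.
- Power: the sample-size inversion is cross-checked against a direct
  scipy noncentral-t power computation and a seeded t-test simulation
  (1500 reps) within a 3-SE binomial envelope of the analytic power.

## Known limitations

- Band boundaries and the denominator floor are disambiguations of an
  underspecified published convention (documented above).
- The control group-level row is only reproducible from its published
  component ratios; the underlying control BSC 3–5 stratum medians were
  never printed.
- The generator's independence assumption makes joint statistics of the
  index conservative relative to a correlated reality.
- Units are µmol/mmol creatinine throughout; no conversion from the µg/mg
  calibration-range units quoted for the assay is attempted (the bridge is
  not given).
- No covariate adjustment (age, sex) is performed, matching the source
  analysis; demographic imbalance is reported descriptively.
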