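"""Seeded synthetic cohorts calibrated to the published summary tables.

No subject-level data are deposited for this study, so every pipeline
stage is exercised against generated cohorts whose stratum sizes, sex and
age structure, and per-analyte median/(Q1, Q3) summaries emulate the
published tables.  Each analyte in each stratum is drawn from a
log-normal fitted to that stratum's printed quartile summary: with
median m and quartiles (q1, q3),

    mu    = ln(m)
    sigma = ln(q3/q1) / (2 z),   z = 0.674490 (the N(0,1) third quartile)

which reproduces the median and the quartile *ratio* exactly — a
two-parameter family cannot also match both quartiles individually.
Log-normality is a modelling choice motivated by positivity and the
pronounced right skew of every printed summary (Q3−median > median−Q1);
analytes are sampled independently within subject unless a log-scale
correlation matrix is supplied.

Cohorts are emitted in normalized units (µmol/mmol creatinine) directly,
matching the scale the summaries are published on; the creatinine column
is filled with plausible pediatric first-morning values for plumbing
only (the index is creatinine-invariant by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import truncnorm

from .cohort_io import (
    ANALYTES,
    FLAG_BELOW_LOQ,
    FLAG_MISSING,
    FLAG_OK,
    NORMALIZED,
    CohortTable,
    SubjectRecord,
    ToxinEntry,
)

#: standard normal deviate of the third quartile
Z_Q3 = 0.674490

#: strata the generator draws, with group label and BSC member set
GENERATED_STRATA: dict[str, tuple[str, tuple[int, ...]]] = {
    "control": ("control", (3, 4, 5)),
    "asd_hard": ("asd", (1, 2)),
    "asd_loose": ("asd", (6, 7)),
    "asd_normal": ("asd", (3, 4, 5)),
}

# creatinine model (mmol/L): log-normal, median 8, log-sd 0.6
_CREATININE_MU = float(np.log(8.0))
_CREATININE_SIGMA = 0.6


@dataclass(frozen=True)
class LognormalParams:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class AnalyteTarget:
    analyte: str
    group_key: str
    median_target: float
    q1_target: float
    q3_target: float

    def __post_init__(self) -> None:
        if not (0 < self.q1_target <= self.median_target <= self.q3_target):
            raise ValueError(
                f"{self.group_key}/{self.analyte}: need 0 < Q1 <= median <= Q3, "
                f"got ({self.q1_target}, {self.median_target}, {self.q3_target})"
            )


@dataclass(frozen=True)
class AgeModel:
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError("age min must be <= max")


@dataclass
class CohortSpec:
    subgroup_sizes: dict[str, int]
    sex_proportions: dict[str, float]  # fraction boys
    age_models: dict[str, AgeModel]
    analyte_targets: dict[tuple[str, str], AnalyteTarget]  # (group_key, analyte)
    loq_censoring: dict[str, float] = field(default_factory=dict)
    missingness_rate: float = 0.0
    log_correlation: np.ndarray | None = None  # 5x5, analyte order as ANALYTES
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.subgroup_sizes.values()):
            raise ValueError("subgroup sizes must be positive")
        if any(not (0 <= p <= 1) for p in self.sex_proportions.values()):
            raise ValueError("sex proportions must lie in [0, 1]")
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must lie in [0, 1)")
        for key in self.subgroup_sizes:
            gaps = [a for a in ANALYTES if (key, a) not in self.analyte_targets]
            if gaps:
                raise ValueError(f"stratum {key}: no analyte target for {gaps}")


def fit_lognormal_from_quartiles(target: AnalyteTarget) -> LognormalParams:
    """Closed-form log-normal calibration to a median/(Q1, Q3) summary."""
    mu = float(np.log(target.median_target))
    sigma = float(np.log(target.q3_target / target.q1_target) / (2.0 * Z_Q3))
    return LognormalParams(mu=mu, sigma=sigma)


def _reference() -> dict:
    with resources.files("migd.data").joinpath("reference_targets.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


def load_reference_tables() -> dict:
    """The transcribed published summaries (calibration constants)."""
    return _reference()


def default_paper_spec(seed: int = 0) -> CohortSpec:
    """The study-sized spec: 71 controls; 97 ASD split 28 hard / 8 loose / 61 normal.

    Control stool-subgroup summaries are not published, so all control
    strata share the all-control targets, and controls are assigned to the
    normal-stool category (the scale the published control row is labelled
    with).
    """
    ref = _reference()
    sizes: dict[str, int] = {}
    sexes: dict[str, float] = {}
    ages: dict[str, AgeModel] = {}
    targets: dict[tuple[str, str], AnalyteTarget] = {}
    for key in GENERATED_STRATA:
        demo = ref["demographics"][key]
        sizes[key] = int(demo["n"])
        sexes[key] = demo["boys"] / demo["n"]
        ages[key] = AgeModel(
            demo["age_mean"], demo["age_sd"], demo["age_min"], demo["age_max"]
        )
        for analyte in ANALYTES:
            med, q1, q3 = ref["toxin_summaries"][key][analyte]
            targets[(key, analyte)] = AnalyteTarget(analyte, key, med, q1, q3)
    return CohortSpec(
        subgroup_sizes=sizes,
        sex_proportions=sexes,
        age_models=ages,
        analyte_targets=targets,
        seed=seed,
    )


def scaled_spec(n_per_subgroup: int, seed: int = 0) -> CohortSpec:
    """Default spec with every stratum resized (for calibration studies)."""
    spec = default_paper_spec(seed=seed)
    spec.subgroup_sizes = {k: n_per_subgroup for k in spec.subgroup_sizes}
    return spec


def _draw_ages(model: AgeModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.sd == 0:
        return np.full(n, model.mean)
    a = (model.min - model.mean) / model.sd
    b = (model.max - model.mean) / model.sd
    return truncnorm.rvs(a, b, loc=model.mean, scale=model.sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortTable:
    """Draw one cohort; deterministic given (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.log_correlation is None:
        corr = np.eye(len(ANALYTES))
    else:
        corr = np.asarray(spec.log_correlation, dtype=float)
        if corr.shape != (len(ANALYTES), len(ANALYTES)):
            raise ValueError("log_correlation must be 5x5 in ANALYTES order")
    chol = np.linalg.cholesky(corr)

    records: list[SubjectRecord] = []
    sid = 0
    for key, (group, bsc_members) in GENERATED_STRATA.items():
        if key not in spec.subgroup_sizes:
            continue
        n = spec.subgroup_sizes[key]
        params = [
            fit_lognormal_from_quartiles(spec.analyte_targets[(key, a)])
            for a in ANALYTES
        ]
        mus = np.array([p.mu for p in params])
        sigmas = np.array([p.sigma for p in params])
        z = rng.standard_normal((n, len(ANALYTES))) @ chol.T
        values = np.exp(mus + sigmas * z)

        bsc = rng.choice(bsc_members, size=n)
        boys = rng.random(n) < spec.sex_proportions[key]
        ages = _draw_ages(spec.age_models[key], n, rng)
        creatinine = np.exp(_CREATININE_MU + _CREATININE_SIGMA * rng.standard_normal(n))
        below = {
            a: values[:, i] < spec.loq_censoring[a]
            for i, a in enumerate(ANALYTES)
            if a in spec.loq_censoring
        }
        miss = (
            rng.random((n, len(ANALYTES))) < spec.missingness_rate
            if spec.missingness_rate > 0
            else np.zeros((n, len(ANALYTES)), dtype=bool)
        )

        for j in range(n):
            sid += 1
            toxins: dict[str, ToxinEntry] = {}
            for i, a in enumerate(ANALYTES):
                if miss[j, i]:
                    toxins[a] = ToxinEntry(None, FLAG_MISSING)
                elif a in below and below[a][j]:
                    toxins[a] = ToxinEntry(None, FLAG_BELOW_LOQ)
                else:
                    toxins[a] = ToxinEntry(float(values[j, i]), FLAG_OK)
            records.append(
                SubjectRecord(
                    subject_id=f"S{sid:05d}",
                    group=group,
                    sex="boy" if boys[j] else "girl",
                    age_years=float(np.round(ages[j], 2)),
                    bsc_type=int(bsc[j]),
                    creatinine=float(np.round(creatinine[j], 3)),
                    toxins=toxins,
                    unit_state=NORMALIZED,
                )
            )
    table = CohortTable(
        records=records,
        provenance=f"synthetic:seed={spec.seed if seed is None else seed}",
    )
    return table
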