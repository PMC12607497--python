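import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from migd.cohort_io import CohortTable, SubjectRecord, ToxinEntry, ANALYTES, NORMALIZED

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    sid="S1", group="asd", sex="boy", age=8.0, bsc=2, creatinine=8.0,
    unit_state=NORMALIZED, **toxins,
):
    """Record with explicit toxin values; unset analytes default to 1.0."""
    entries = {}
    for a in ANALYTES:
        v = toxins.get(a, 1.0)
        if v is None:
            entries[a] = ToxinEntry(None, "missing")
        else:
            entries[a] = ToxinEntry(float(v), "ok")
    return SubjectRecord(
        subject_id=sid, group=group, sex=sex, age_years=age, bsc_type=bsc,
        creatinine=creatinine, toxins=entries, unit_state=unit_state,
    )


def make_cohort_from_arrays(group_specs, rng=None):
    """Fast cohort builder: list of (group, bsc_type, values_by_analyte dict of arrays)."""
    records = []
    sid = 0
    for group, bsc, values in group_specs:
        n = len(next(iter(values.values())))
        for j in range(n):
            sid += 1
            records.append(
                make_record(
                    sid=f"X{sid:05d}", group=group, bsc=bsc,
                    **{a: float(values[a][j]) for a in values},
                )
            )
    return CohortTable(records=records, provenance="test")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cohort():
    """Three hard-stool ASD subjects and three normal-stool controls."""
    recs = [
        make_record(sid="A1", group="asd", bsc=1, PCS=46.65, TMAO=2.38, IS=52.26, ADMA=14.79),
        make_record(sid="A2", group="asd", bsc=2, PCS=40.0, TMAO=2.0, IS=50.0, ADMA=12.0),
        make_record(sid="A3", group="asd", bsc=2, PCS=50.0, TMAO=3.0, IS=60.0, ADMA=15.0),
        make_record(sid="C1", group="control", bsc=4, PCS=37.74, TMAO=3.09, IS=63.80, ADMA=12.70),
        make_record(sid="C2", group="control", bsc=3, PCS=30.0, TMAO=3.0, IS=55.0, ADMA=10.0),
        make_record(sid="C3", group="control", bsc=5, PCS=45.0, TMAO=4.0, IS=70.0, ADMA=14.0),
    ]
    return CohortTable(records=recs, provenance="fixture")
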