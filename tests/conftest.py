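import numpy as np
import pytest

from endorisk.cohort import Cohort, PatientRecord


def make_record(pid="P1", **overrides) -> PatientRecord:
    """A clinically unremarkable baseline patient; override what the test needs."""
    base = dict(
        patient_id=pid,
        age_years=65.0,
        histology="EEC",
        grade="G1",
        myometrial_invasion="lt50",
        figo_stage="IA",
        lvsi="negative",
        pole_variant="",
        mmr_status="proficient",
        p53_ihc="wildtype",
        ctnnb1_exon3="wildtype",
        er="positive",
        pr="positive",
        ecad="positive",
        her2="negative",
        arid1a="negative",
        pten="negative",
        l1cam="negative",
        rfs_time_months=80.0,
        rfs_event=False,
        os_time_months=80.0,
        os_event=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort():
    records = [
        make_record("P1"),
        make_record("P2", grade="G3", figo_stage="IB", myometrial_invasion="ge50",
                    rfs_time_months=24.0, rfs_event=True, os_time_months=40.0, os_event=True),
        make_record("P3", histology="NEEC", grade="G3", p53_ihc="abnormal",
                    rfs_time_months=12.0, rfs_event=True, os_time_months=30.0, os_event=False),
    ]
    return Cohort.from_records(records)


def harrell_pairs_bruteforce(scores, time, event):
    """Independent O(n^2) pair enumeration of the censoring-aware concordance.

    A pair is permissible iff the patient with the smaller observed time had
    an event; tied times are permissible iff exactly one is an event (the
    event patient is the shorter-lived one).  Concordant iff the
    shorter-lived patient has the strictly higher score; score ties are
    counted separately.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    conc = disc = tied = 0
    n = len(time)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if event[i] == event[j]:
                    continue
                short, long_ = (i, j) if event[i] else (j, i)
            elif time[i] < time[j]:
                if not event[i]:
                    continue
                short, long_ = i, j
            else:
                if not event[j]:
                    continue
                short, long_ = j, i
            if scores[short] > scores[long_]:
                conc += 1
            elif scores[short] < scores[long_]:
                disc += 1
            else:
                tied += 1
    return conc, disc, tied
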