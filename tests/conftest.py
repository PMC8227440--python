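import datetime as dt

import pytest

from msclassify.data_model import Cohort, Patient, Relapse, Visit

EPOCH = dt.date(2000, 1, 1)


def months(m: float) -> dt.date:
    """Date m months after the epoch (30.4-day months, for rule traces)."""
    return EPOCH + dt.timedelta(days=round(m * 30.4375))


def make_patient(pid="p1", sex="female", birth=dt.date(1960, 1, 1),
                 onset=dt.date(1990, 1, 1), phenotype="RR", sp_date=None) -> Patient:
    return Patient(pid, sex, birth, onset, phenotype, sp_date)


def series_cohort(series, relapse_months=(), pid="p1", phenotype="RR", sp_date=None):
    """Cohort of one patient whose EDSS history is [(month, edss), ...]."""
    patient = make_patient(pid=pid, birth=dt.date(1960, 1, 1),
                           onset=dt.date(1999, 1, 1), phenotype=phenotype,
                           sp_date=sp_date)
    visits = [Visit(pid, months(m), e) for m, e in series]
    relapses = [Relapse(pid, months(m)) for m in relapse_months]
    return Cohort(patients=[patient], visits=visits, relapses=relapses)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Two patients: one clinically RR, one SP with a transition date."""
    p1 = make_patient("a", phenotype="RR")
    p2 = make_patient("b", sex="male", phenotype="SP", sp_date=dt.date(2010, 7, 1))
    visits = [
        Visit("a", dt.date(2010, 1, 1), 2.0),
        Visit("a", dt.date(2018, 1, 1), 5.5),
        Visit("b", dt.date(2012, 3, 1), 6.5),
    ]
    return Cohort(patients=[p1, p2], visits=visits)
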