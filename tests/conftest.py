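from datetime import date

import hypothesis
import pytest

from claimslab import (
    ClinicalEventRecord,
    EventKind,
    PrescriptionRecord,
    Route,
    StudyWindow,
    triptan_dose_table,
)

hypothesis.settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def dose_table():
    return triptan_dose_table()


@pytest.fixture(scope="session")
def window():
    """Eight-month run-in, five fiscal years of analysis."""
    return StudyWindow(date(2010, 8, 1), date(2011, 3, 31), date(2011, 4, 1), date(2016, 3, 31))


@pytest.fixture
def rx():
    """Factory for prescription records with sensible defaults."""

    def make(
        pid="P1",
        d="2012-01-15",
        days=10,
        dose=50.0,
        ingredient="sumatriptan succinate",
        route=Route.SYSTEMIC,
        code="RX",
    ):
        return PrescriptionRecord(
            patient_id=pid,
            drug_code=code,
            ingredient=ingredient,
            route=route,
            dispense_date=date.fromisoformat(d),
            days_supplied=days,
            daily_dose=dose,
        )

    return make


@pytest.fixture
def ev():
    """Factory for clinical-event records."""

    def make(pid="P1", d="2012-01-15", kind=EventKind.DIAGNOSIS, code="DX"):
        return ClinicalEventRecord(
            patient_id=pid, code=code, event_date=date.fromisoformat(d), kind=kind
        )

    return make
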