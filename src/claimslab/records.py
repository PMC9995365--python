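"""Core record types for longitudinal claims data.

A claims dataset, for our purposes, is two event streams per patient: a
prescription stream (dispensing events carrying a daily dose and a number of
days supplied) and a clinical-event stream (diagnosis and procedure claims).
Both are held at day resolution; any month-level logic downstream is derived
from the stored dates, never by truncating them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date


class Route(str, enum.Enum):
    """Administration route of a dispensed drug."""

    SYSTEMIC = "systemic"
    TOPICAL_NON_OPHTHALMIC = "topical_non_ophthalmic"
    OPHTHALMIC = "ophthalmic"


class EventKind(str, enum.Enum):
    """Whether a clinical claim records a diagnosis or a procedure."""

    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"


@dataclass(frozen=True, slots=True)
class PrescriptionRecord:
    """One dispensing event.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    drug_code : str
        Product-level code of the dispensed drug.
    ingredient : str
        Active-ingredient name; keys into a :class:`DoseEquivalenceTable`.
    route : Route
        Administration route.
    dispense_date : datetime.date
        Day the prescription was dispensed (supply starts this day).
    days_supplied : int
        Number of days the supply covers; at least 1.
    daily_dose : float
        Prescribed dose per day in mg; strictly positive.
    """

    patient_id: str
    drug_code: str
    ingredient: str
    route: Route
    dispense_date: date
    days_supplied: int
    daily_dose: float

    def __post_init__(self) -> None:
        if not isinstance(self.dispense_date, date):
            raise TypeError("dispense_date must be a datetime.date")
        if int(self.days_supplied) != self.days_supplied or self.days_supplied < 1:
            raise ValueError(f"days_supplied must be an integer >= 1, got {self.days_supplied}")
        if not self.daily_dose > 0:
            raise ValueError(f"daily_dose must be > 0, got {self.daily_dose}")
        object.__setattr__(self, "route", Route(self.route))
        object.__setattr__(self, "days_supplied", int(self.days_supplied))
        object.__setattr__(self, "daily_dose", float(self.daily_dose))

    @property
    def supply_end(self) -> date:
        """Last day covered by this dispensing (inclusive)."""
        from datetime import timedelta

        return self.dispense_date + timedelta(days=self.days_supplied - 1)


@dataclass(frozen=True, slots=True)
class ClinicalEventRecord:
    """A diagnosis or procedure claim."""

    patient_id: str
    code: str
    event_date: date
    kind: EventKind

    def __post_init__(self) -> None:
        if not isinstance(self.event_date, date):
            raise TypeError("event_date must be a datetime.date")
        object.__setattr__(self, "kind", EventKind(self.kind))


@dataclass(frozen=True, slots=True)
class StudyWindow:
    """Study calendar: data span, run-in (washout) span and analysis span.

    The run-in period ``[data_start, run_in_end]`` is observed only to
    establish that later first events are truly incident; events falling in
    it trigger exclusion downstream.  The analysis span
    ``[analysis_start, analysis_end]`` is where incidence is measured.
    """

    data_start: date
    run_in_end: date
    analysis_start: date
    analysis_end: date

    def __post_init__(self) -> None:
        if not (self.data_start <= self.run_in_end < self.analysis_start <= self.analysis_end):
            raise ValueError(
                "StudyWindow requires data_start <= run_in_end < analysis_start <= analysis_end, "
                f"got {self.data_start}, {self.run_in_end}, {self.analysis_start}, {self.analysis_end}"
            )

    def in_run_in(self, d: date) -> bool:
        return self.data_start <= d <= self.run_in_end

    def in_analysis(self, d: date) -> bool:
        return self.analysis_start <= d <= self.analysis_end
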