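"""Drug-utilization analyses over prescription claims.

Three study patterns are implemented, all per-patient aggregations of a
prescription stream:

* **Overuse phenotyping** — monthly dose totals are converted to
  reference-ingredient equivalents and screened against two criteria
  modelled on the ICHD-3 medication-overuse idea (regular intake of acute
  medication on 10 or more days per month for months on end): either the
  monthly equivalent total exceeds ten reference doses in four or more
  consecutive calendar months, or a single month exceeds an integral
  multiple X >= 4 of that threshold (a bulk supply) and a further
  prescription follows within X months (evidence the supply was consumed).
  Run with the single-dose basis the phenotype reads "suspected overuse";
  with the max-daily-dose basis, the stricter "overuse".

* **Cumulative dose** — the plain sum of daily dose times days supplied per
  patient; dose is additive, so overlapping supplies are *not* merged here.

* **Prescription duration** — treated time per patient as the size of the
  union of supply intervals (overlap days counted once), the per-patient
  daily dose as cumulative dose over merged days, and fiscal-year sub-cohorts
  keyed to each patient's first prescription (first dates inside the run-in
  span are excluded as non-incident).

Each pattern is exposed both as plain functions and as a Model class whose
``fit()`` returns a Results object with a ``summary()`` table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dates import MonthKey, fiscal_year, month_from_index, month_index, month_key
from .equivalence import DoseBasis, DoseEquivalenceTable
from .records import PrescriptionRecord, StudyWindow

#: Cohort marker for patients whose first prescription falls in the run-in span.
EXCLUDED = "excluded"

CONSECUTIVE_MONTHS_REQUIRED = 4  # criterion 1: months above threshold, no gap
THRESHOLD_MULTIPLE = 10  # both criteria: 10 reference doses per month
MIN_BULK_MULTIPLE = 4  # criterion 2: X >= 4


class OveruseStatus(str, enum.Enum):
    NONE = "none"
    SUSPECTED_OVERUSE = "suspected_overuse"
    OVERUSE = "overuse"


class OveruseCriterion(str, enum.Enum):
    CONSECUTIVE_MONTHS = "consecutive_months"
    MULTIPLE_WITH_REFILL = "multiple_with_refill"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class MonthlyDoseSeries:
    """Per-patient monthly totals in reference-equivalent mg.

    ``totals`` covers every calendar month of the patient's observed span
    (first to last prescription month inclusive) with zeros where nothing
    was dispensed; ``rx_months`` marks months with at least one dispensing.
    """

    patient_id: str
    totals: dict[MonthKey, float]
    rx_months: frozenset[MonthKey]

    def months(self) -> list[MonthKey]:
        return list(self.totals)


@dataclass(frozen=True)
class OveruseAssessment:
    patient_id: str
    status: OveruseStatus
    triggering_criterion: OveruseCriterion
    trigger_month: MonthKey | None = None
    multiplier_x: int | None = None

    def __post_init__(self) -> None:
        if (self.status is OveruseStatus.NONE) != (
            self.triggering_criterion is OveruseCriterion.NOT_APPLICABLE
        ):
            raise ValueError("status none iff criterion not_applicable")
        if self.multiplier_x is not None and (
            self.triggering_criterion is not OveruseCriterion.MULTIPLE_WITH_REFILL
        ):
            raise ValueError("multiplier_x only applies to multiple_with_refill")


@dataclass(frozen=True)
class ExposureSummary:
    """Per-patient exposure for the duration study."""

    patient_id: str
    cumulative_dose: float
    cumulative_days: int
    first_rx_date: date
    daily_dose_per_patient: float
    fiscal_cohort: int | str


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": self.min,
            "max": self.max,
        }


@dataclass(frozen=True)
class HistogramBin:
    lower: float
    upper: float  # half-open: [lower, upper)
    count: int


# ---------------------------------------------------------------------------
# operations


def monthly_equivalent_dose(
    records: Sequence[PrescriptionRecord],
    eq: DoseEquivalenceTable,
    basis: DoseBasis,
) -> MonthlyDoseSeries:
    """Total reference-equivalent dose per calendar month for one patient.

    Each prescription contributes ``daily_dose * days_supplied`` mg of its
    own ingredient, converted to reference mg by the basis-dose ratio, and
    is attributed wholly to the month of its dispense date.
    """
    if not records:
        raise ValueError("monthly_equivalent_dose requires at least one record")
    pids = {r.patient_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}")
    raw: dict[MonthKey, float] = {}
    for r in records:
        key = month_key(r.dispense_date)
        raw[key] = raw.get(key, 0.0) + r.daily_dose * r.days_supplied * eq.ratio(r.ingredient, basis)
    lo = min(month_index(k) for k in raw)
    hi = max(month_index(k) for k in raw)
    totals = {month_from_index(i): raw.get(month_from_index(i), 0.0) for i in range(lo, hi + 1)}
    return MonthlyDoseSeries(patient_id=pids.pop(), totals=totals, rx_months=frozenset(raw))


def _largest_multiple_below(total: float, threshold: float) -> int:
    """Largest integer X with total > X * threshold (strict)."""
    x = math.floor(total / threshold)
    if not total > x * threshold:  # exact multiple, or float rounding up
        x -= 1
    return x


def classify_overuse(
    series: MonthlyDoseSeries,
    eq: DoseEquivalenceTable,
    basis: DoseBasis,
) -> OveruseAssessment:
    """Apply the two overuse criteria to one patient's monthly series.

    The monthly threshold is T = 10 x (reference basis dose); "exceeded" is
    strict.  The earliest triggering month wins; on a tie the
    consecutive-months criterion takes precedence.  Status is
    ``suspected_overuse`` under the single-dose basis and ``overuse`` under
    the max-daily-dose basis.
    """
    threshold = THRESHOLD_MULTIPLE * eq.reference_dose(basis)
    months = series.months()
    totals = [series.totals[m] for m in months]

    trigger1: MonthKey | None = None
    run = 0
    for i, tot in enumerate(totals):
        run = run + 1 if tot > threshold else 0
        if run == CONSECUTIVE_MONTHS_REQUIRED:
            trigger1 = months[i - (CONSECUTIVE_MONTHS_REQUIRED - 1)]
            break

    trigger2: MonthKey | None = None
    multiplier: int | None = None
    rx_idx = {month_index(m) for m in series.rx_months}
    for m, tot in zip(months, totals):
        x = _largest_multiple_below(tot, threshold)
        if x < MIN_BULK_MULTIPLE:
            continue
        mi = month_index(m)
        if any(j in rx_idx for j in range(mi + 1, mi + x + 1)):
            trigger2 = m
            multiplier = x
            break

    status = (
        OveruseStatus.SUSPECTED_OVERUSE if basis == "single_dose" else OveruseStatus.OVERUSE
    )
    if trigger1 is not None and (
        trigger2 is None or month_index(trigger1) <= month_index(trigger2)
    ):
        return OveruseAssessment(
            series.patient_id, status, OveruseCriterion.CONSECUTIVE_MONTHS, trigger1
        )
    if trigger2 is not None:
        return OveruseAssessment(
            series.patient_id,
            status,
            OveruseCriterion.MULTIPLE_WITH_REFILL,
            trigger2,
            multiplier,
        )
    return OveruseAssessment(series.patient_id, OveruseStatus.NONE, OveruseCriterion.NOT_APPLICABLE)


def cumulative_dose(records: Iterable[PrescriptionRecord]) -> float:
    """Sum of daily_dose x days_supplied in mg; overlaps are not merged."""
    return float(sum(r.daily_dose * r.days_supplied for r in records))


def merged_prescription_days(records: Iterable[PrescriptionRecord]) -> int:
    """Days covered by at least one supply interval; overlap days count once."""
    intervals = sorted(
        (r.dispense_date.toordinal(), r.dispense_date.toordinal() + r.days_supplied - 1)
        for r in records
    )
    total = 0
    cur_start: int | None = None
    cur_end = -1
    for start, end in intervals:
        if cur_start is None or start > cur_end + 1:
            if cur_start is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def assign_subcohorts(
    first_dates: Mapping[str, date], window: StudyWindow
) -> dict[str, int | str]:
    """Fiscal-year cohort of each patient's first prescription.

    First dates inside the run-in span map to :data:`EXCLUDED`; dates outside
    the data window are an error (they contradict the first-date premise).
    """
    out: dict[str, int | str] = {}
    for pid, d in first_dates.items():
        if d < window.data_start or d > window.analysis_end:
            raise ValueError(
                f"first prescription {d} for patient {pid!r} lies outside the data window"
            )
        out[pid] = EXCLUDED if window.in_run_in(d) else fiscal_year(d)
    return out


def summarize(values: Sequence[float]) -> SummaryStats:
    """Location/spread summary with linear-interpolation quartiles and sample SD.

    The SD uses the n-1 denominator; for a single value it is reported as 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires a non-empty list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def frequency_distribution(values: Sequence[float], bin_width: float) -> list[HistogramBin]:
    """Counts over half-open bins [k*w, (k+1)*w); interior empty bins included."""
    if not bin_width > 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return []
    ks = np.floor(arr / bin_width).astype(int)
    k_lo, k_hi = int(ks.min()), int(ks.max())
    counts = np.bincount(ks - k_lo, minlength=k_hi - k_lo + 1)
    return [
        HistogramBin(lower=(k_lo + i) * bin_width, upper=(k_lo + i + 1) * bin_width, count=int(c))
        for i, c in enumerate(counts)
    ]


def _group_by_patient(
    records: Iterable[PrescriptionRecord],
) -> dict[str, list[PrescriptionRecord]]:
    groups: dict[str, list[PrescriptionRecord]] = {}
    for r in records:
        groups.setdefault(r.patient_id, []).append(r)
    return groups


# ---------------------------------------------------------------------------
# model classes


class OveruseStudy:
    """Overuse phenotyping over a prescription table.

    Parameters
    ----------
    prescriptions : sequence of PrescriptionRecord
    dose_table : DoseEquivalenceTable
        Must cover every ingredient appearing in the data.
    """

    def __init__(
        self,
        prescriptions: Sequence[PrescriptionRecord],
        dose_table: DoseEquivalenceTable,
    ):
        self.prescriptions = list(prescriptions)
        self.dose_table = dose_table

    def fit(self, basis: DoseBasis = "single_dose") -> "OveruseResults":
        assessments = []
        for pid, recs in _group_by_patient(self.prescriptions).items():
            series = monthly_equivalent_dose(recs, self.dose_table, basis)
            assessments.append(classify_overuse(series, self.dose_table, basis))
        return OveruseResults(self, basis, assessments)


@dataclass
class OveruseResults:
    model: OveruseStudy
    basis: DoseBasis
    assessments: list[OveruseAssessment]

    @property
    def n_patients(self) -> int:
        return len(self.assessments)

    @property
    def n_flagged(self) -> int:
        return sum(a.status is not OveruseStatus.NONE for a in self.assessments)

    @property
    def prevalence(self) -> float:
        return self.n_flagged / self.n_patients if self.n_patients else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": a.patient_id,
                    "status": a.status.value,
                    "criterion": a.triggering_criterion.value,
                    "trigger_month": (
                        f"{a.trigger_month[0]:04d}-{a.trigger_month[1]:02d}"
                        if a.trigger_month
                        else ""
                    ),
                    "multiplier_x": a.multiplier_x if a.multiplier_x is not None else "",
                }
                for a in self.assessments
            ]
        )

    def summary(self) -> str:
        label = "suspected overuse" if self.basis == "single_dose" else "overuse"
        by_crit = {c: 0 for c in OveruseCriterion}
        for a in self.assessments:
            by_crit[a.triggering_criterion] += 1
        lines = [
            "Overuse phenotyping",
            "=" * 46,
            f"Dose basis:              {self.basis}",
            f"Patients analysed:       {self.n_patients}",
            f"Flagged ({label}): {self.n_flagged} ({100 * self.prevalence:.2f}%)",
            f"  via consecutive months: {by_crit[OveruseCriterion.CONSECUTIVE_MONTHS]}",
            f"  via bulk multiple + refill: {by_crit[OveruseCriterion.MULTIPLE_WITH_REFILL]}",
        ]
        return "\n".join(lines)


class CumulativeDoseStudy:
    """Cumulative dose per patient with summary statistics and a histogram."""

    def __init__(self, prescriptions: Sequence[PrescriptionRecord]):
        self.prescriptions = list(prescriptions)

    def fit(self, bin_width: float = 10_000.0) -> "CumulativeDoseResults":
        doses = {
            pid: cumulative_dose(recs)
            for pid, recs in _group_by_patient(self.prescriptions).items()
        }
        stats = summarize(list(doses.values())) if doses else None
        hist = frequency_distribution(list(doses.values()), bin_width)
        return CumulativeDoseResults(self, doses, stats, hist, bin_width)


@dataclass
class CumulativeDoseResults:
    model: CumulativeDoseStudy
    doses: dict[str, float]
    stats: SummaryStats | None
    histogram: list[HistogramBin]
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"patient_id": p, "cumulative_dose_mg": d} for p, d in self.doses.items()]
        )

    def summary(self) -> str:
        if self.stats is None:
            return "Cumulative dose: no patients"
        s = self.stats
        return "\n".join(
            [
                "Cumulative dose per patient (mg)",
                "=" * 46,
                f"Patients:  {s.n}",
                f"Mean (SD): {s.mean:.1f} ({s.sd:.1f})",
                f"Median [IQR]: {s.median:.1f} [{s.q1:.1f}-{s.q3:.1f}]",
                f"Range: {s.min:.1f}-{s.max:.1f}",
                f"Histogram bins ({self.bin_width:g} mg wide): {len(self.histogram)}",
            ]
        )


class DurationStudy:
    """Merged prescription days and daily dose per patient, by fiscal cohort.

    Patients whose first prescription falls in the run-in span are retained
    in the output with cohort :data:`EXCLUDED` but dropped from per-cohort
    statistics.
    """

    def __init__(self, prescriptions: Sequence[PrescriptionRecord], window: StudyWindow):
        self.prescriptions = list(prescriptions)
        self.window = window

    def fit(self) -> "DurationResults":
        groups = _group_by_patient(self.prescriptions)
        first_dates = {pid: min(r.dispense_date for r in recs) for pid, recs in groups.items()}
        cohorts = assign_subcohorts(first_dates, self.window)
        summaries = []
        for pid, recs in groups.items():
            dose = cumulative_dose(recs)
            days = merged_prescription_days(recs)
            summaries.append(
                ExposureSummary(
                    patient_id=pid,
                    cumulative_dose=dose,
                    cumulative_days=days,
                    first_rx_date=first_dates[pid],
                    daily_dose_per_patient=dose / days if days else float("nan"),
                    fiscal_cohort=cohorts[pid],
                )
            )
        return DurationResults(self, summaries)


@dataclass
class DurationResults:
    model: DurationStudy
    summaries: list[ExposureSummary]

    @property
    def n_excluded(self) -> int:
        return sum(s.fiscal_cohort == EXCLUDED for s in self.summaries)

    def cohorts(self) -> list[int]:
        return sorted({s.fiscal_cohort for s in self.summaries if s.fiscal_cohort != EXCLUDED})

    def cohort_stats(self, metric: str = "cumulative_days") -> dict[int, SummaryStats]:
        """Per-cohort summaries of ``cumulative_days`` or ``daily_dose_per_patient``."""
        out = {}
        for c in self.cohorts():
            vals = [getattr(s, metric) for s in self.summaries if s.fiscal_cohort == c]
            out[c] = summarize(vals)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "first_rx_date": s.first_rx_date.isoformat(),
                    "fiscal_cohort": s.fiscal_cohort,
                    "cumulative_dose_mg": s.cumulative_dose,
                    "cumulative_days": s.cumulative_days,
                    "daily_dose_mg": s.daily_dose_per_patient,
                }
                for s in self.summaries
            ]
        )

    def summary(self) -> str:
        lines = [
            "Prescription duration by fiscal-year cohort",
            "=" * 60,
            f"Patients: {len(self.summaries)}  (run-in excluded: {self.n_excluded})",
            f"{'cohort':>6} {'n':>7} {'median d':>9} {'IQR (days)':>17}",
        ]
        for c, s in self.cohort_stats("cumulative_days").items():
            lines.append(f"{c:>6} {s.n:>7} {s.median:>9.0f} {s.q1:>8.0f}-{s.q3:<8.0f}")
        return "\n".join(lines)
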