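"""Sequence symmetry analysis (SSA) for safety-signal detection.

SSA asks, among patients who newly start a drug (the exposure) and newly
experience an outcome within a fixed window of each other, whether
exposure-before-outcome is more common than outcome-before-exposure.  Under
no association and stationary incidence the two orders are equally likely,
so the crude sequence ratio

    CSR = n_exposure_first / n_outcome_first

is about 1.  Calendar trends break that symmetry: if initiation of the drug
is rising over the study period, a random incident exposure tends to fall
late and outcome-first pairs are favoured even under the null.  The
null-effect sequence ratio (NESR) quantifies this trend-induced asymmetry
by pairing a random incident exposure with a random incident outcome drawn
independently from the marginal incidence curves, under the same gap
restriction and same-day exclusion as the cohort:

    A = sum_t e_t * sum_{t < s <= t+g} o_s      (exposure first)
    B = sum_t e_t * sum_{t-g <= s < t} o_s      (outcome first)
    NESR = A / B

with e_t, o_t the daily counts of incident exposures and outcomes and g the
maximum gap in days.  The adjusted sequence ratio ASR = CSR / NESR is about
1 under the null regardless of trend.  Confidence intervals treat the
exposure-first count as binomial(n1 + n2, p) with an exact Clopper-Pearson
interval on p, mapped through the odds transform r = p / (1 - p) and divided
by the NESR.

Cohort construction mirrors incident-user practice: first-ever exposure and
first-ever outcome per patient; patients with either first event in the
run-in span are excluded (the event is not demonstrably incident), as are
same-date pairs (order undefined) and pairs further apart than the gap.
The outcome here is an event qualified by a diagnosis claim and a procedure
claim in the same calendar month, anchored to the procedure date.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dates import month_key, window_length_days
from .records import ClinicalEventRecord, EventKind, PrescriptionRecord, Route, StudyWindow


class PairOrder(str, enum.Enum):
    EXPOSURE_FIRST = "exposure_first"
    OUTCOME_FIRST = "outcome_first"


@dataclass(frozen=True, slots=True)
class IncidentPair:
    patient_id: str
    first_exposure_date: date
    first_outcome_date: date
    order: PairOrder
    gap_days: int

    def __post_init__(self) -> None:
        gap = abs((self.first_outcome_date - self.first_exposure_date).days)
        if gap < 1 or gap != self.gap_days:
            raise ValueError(f"gap_days {self.gap_days} inconsistent with dates (|diff| = {gap})")
        expected = (
            PairOrder.EXPOSURE_FIRST
            if self.first_exposure_date < self.first_outcome_date
            else PairOrder.OUTCOME_FIRST
        )
        if self.order is not expected:
            raise ValueError("order inconsistent with dates")


@dataclass(frozen=True)
class IncidenceCurves:
    """Daily counts of incident exposures and outcomes over the analysis window."""

    start: date
    exposures: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.exposures) != len(self.outcomes):
            raise ValueError("curves must share a length")
        if (np.asarray(self.exposures) < 0).any() or (np.asarray(self.outcomes) < 0).any():
            raise ValueError("incidence counts must be >= 0")

    @classmethod
    def from_first_dates(
        cls,
        exposure_firsts: Iterable[date],
        outcome_firsts: Iterable[date],
        window: StudyWindow,
    ) -> "IncidenceCurves":
        n = window_length_days(window.analysis_start, window.analysis_end)
        e = np.zeros(n, dtype=np.int64)
        o = np.zeros(n, dtype=np.int64)
        for d in exposure_firsts:
            if window.in_analysis(d):
                e[(d - window.analysis_start).days] += 1
        for d in outcome_firsts:
            if window.in_analysis(d):
                o[(d - window.analysis_start).days] += 1
        return cls(start=window.analysis_start, exposures=e, outcomes=o)


@dataclass(frozen=True)
class SsaResult:
    n_exposure_first: int
    n_outcome_first: int
    csr: float
    nesr: float
    asr: float
    ci_low: float | None
    ci_high: float | None
    alpha: float
    attrition: dict[str, int]

    @property
    def is_empty(self) -> bool:
        return self.n_exposure_first + self.n_outcome_first == 0


def derive_outcome_events(events: Iterable[ClinicalEventRecord]) -> dict[str, date]:
    """First outcome date per patient.

    A patient-month qualifies when it holds at least one diagnosis and at
    least one procedure claim; that month's outcome date is its earliest
    procedure date, and the patient's outcome is the earliest qualifying
    date over months.
    """
    diag_months: dict[str, set] = {}
    proc_dates: dict[tuple[str, tuple[int, int]], date] = {}
    for ev in events:
        mk = month_key(ev.event_date)
        if ev.kind is EventKind.DIAGNOSIS:
            diag_months.setdefault(ev.patient_id, set()).add(mk)
        else:
            key = (ev.patient_id, mk)
            if key not in proc_dates or ev.event_date < proc_dates[key]:
                proc_dates[key] = ev.event_date
    out: dict[str, date] = {}
    for (pid, mk), d in proc_dates.items():
        if mk in diag_months.get(pid, ()):
            if pid not in out or d < out[pid]:
                out[pid] = d
    return out


def first_exposure_dates(exposures: Iterable[PrescriptionRecord]) -> dict[str, date]:
    """First-ever dispense date per patient."""
    out: dict[str, date] = {}
    for r in exposures:
        if r.patient_id not in out or r.dispense_date < out[r.patient_id]:
            out[r.patient_id] = r.dispense_date
    return out


def _pairs_and_attrition(
    exposure_firsts: Mapping[str, date],
    outcome_firsts: Mapping[str, date],
    window: StudyWindow,
    max_gap: int,
) -> tuple[list[IncidentPair], dict[str, int]]:
    both = sorted(set(exposure_firsts) & set(outcome_firsts))
    attrition = {
        "patients_with_exposure": len(exposure_firsts),
        "patients_with_outcome": len(outcome_firsts),
        "patients_with_both": len(both),
        "excluded_run_in": 0,
        "excluded_same_date": 0,
        "excluded_gap": 0,
        "analyzed": 0,
    }
    pairs: list[IncidentPair] = []
    for pid in both:
        e, o = exposure_firsts[pid], outcome_firsts[pid]
        if window.in_run_in(e) or window.in_run_in(o):
            attrition["excluded_run_in"] += 1
            continue
        if e == o:
            attrition["excluded_same_date"] += 1
            continue
        gap = abs((o - e).days)
        if gap > max_gap:
            attrition["excluded_gap"] += 1
            continue
        order = PairOrder.EXPOSURE_FIRST if e < o else PairOrder.OUTCOME_FIRST
        pairs.append(IncidentPair(pid, e, o, order, gap))
        attrition["analyzed"] += 1
    return pairs, attrition


def build_incident_pairs(
    exposures: Sequence[PrescriptionRecord],
    outcomes: Mapping[str, date],
    window: StudyWindow,
    max_gap: int = 90,
) -> list[IncidentPair]:
    """Incident exposure/outcome pairs after run-in, same-date and gap exclusions."""
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")
    pairs, _ = _pairs_and_attrition(first_exposure_dates(exposures), outcomes, window, max_gap)
    return pairs


def crude_sequence_ratio(pairs: Sequence[IncidentPair]) -> tuple[int, int, float]:
    """Counts in each order and their ratio (inf/nan when a direction is empty)."""
    n1 = sum(p.order is PairOrder.EXPOSURE_FIRST for p in pairs)
    n2 = len(pairs) - n1
    if n2 == 0:
        csr = float("nan") if n1 == 0 else float("inf")
    else:
        csr = n1 / n2
    return n1, n2, csr


def null_effect_sequence_ratio(
    curves: IncidenceCurves, max_gap: int, restricted: bool = True
) -> float:
    """Expected sequence ratio under independence of the marginal curves.

    With ``restricted=True`` (default) the null pairing honours the same
    gap restriction and same-day exclusion as the cohort.  With
    ``restricted=False`` the classical unrestricted form is used (every
    ordered pair of distinct days counts, whatever the gap).
    """
    e = np.asarray(curves.exposures, dtype=float)
    o = np.asarray(curves.outcomes, dtype=float)
    n = len(e)
    c = np.concatenate([[0.0], np.cumsum(o)])  # c[k] = sum of o[0:k]
    t = np.arange(n)
    if restricted:
        future = c[np.minimum(t + max_gap, n - 1) + 1] - c[t + 1]
        past = c[t] - c[np.maximum(t - max_gap, 0)]
    else:
        future = c[n] - c[t + 1]
        past = c[t]
    a = float(np.dot(e, future))
    b = float(np.dot(e, past))
    if b == 0.0:
        return float("nan") if a == 0.0 else float("inf")
    return a / b


def adjusted_sequence_ratio(csr: float, nesr: float) -> float:
    if not (np.isfinite(csr) and np.isfinite(nesr)) or csr <= 0 or nesr <= 0:
        raise ValueError(f"csr and nesr must be finite and positive, got {csr}, {nesr}")
    return csr / nesr


def sequence_ratio_ci(
    n1: int,
    n2: int,
    nesr: float = 1.0,
    alpha: float = 0.05,
    method: str = "clopper_pearson",
) -> tuple[float, float]:
    """Two-sided (1 - alpha) interval for the adjusted sequence ratio.

    n1 is modelled as binomial(n1 + n2, p); an exact Clopper-Pearson
    interval (or Wilson score with ``method="wilson"``) on p is pushed
    through r = p / (1 - p) and divided by the NESR.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n1 < 1 or n2 < 1:
        raise ValueError("sequence_ratio_ci requires n1 >= 1 and n2 >= 1")
    n = n1 + n2
    if method == "clopper_pearson":
        p_lo = stats.beta.ppf(alpha / 2, n1, n2 + 1)
        p_hi = stats.beta.ppf(1 - alpha / 2, n1 + 1, n2)
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        p_lo, p_hi = proportion_confint(n1, n, alpha=alpha, method="wilson")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (p_lo / (1 - p_lo)) / nesr, (p_hi / (1 - p_hi)) / nesr


def run_ssa(
    exposures: Sequence[PrescriptionRecord],
    clinical_events: Sequence[ClinicalEventRecord],
    window: StudyWindow,
    route_filter: set[Route] | None = None,
    max_gap: int = 90,
    alpha: float = 0.05,
    restricted_nesr: bool = True,
    ci_method: str = "clopper_pearson",
) -> SsaResult:
    """End-to-end SSA: outcome derivation, pairing, CSR, NESR, ASR, CI.

    The incidence curves feeding the NESR come from the first-ever event
    dates of the whole post-run-in population (before the gap pairing
    restriction); a patient with any first event in the run-in span is
    excluded throughout.
    """
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")
    if route_filter is not None:
        routes = {Route(r) for r in route_filter}
        exposures = [r for r in exposures if r.route in routes]

    exp_firsts = first_exposure_dates(exposures)
    out_firsts = derive_outcome_events(clinical_events)
    pairs, attrition = _pairs_and_attrition(exp_firsts, out_firsts, window, max_gap)
    n1, n2, csr = crude_sequence_ratio(pairs)

    def _clean(firsts: Mapping[str, date]) -> list[date]:
        # run-in exclusion is per patient: either first event in run-in drops them
        return [
            d
            for pid, d in firsts.items()
            if not (
                window.in_run_in(d)
                or (pid in exp_firsts and window.in_run_in(exp_firsts[pid]))
                or (pid in out_firsts and window.in_run_in(out_firsts[pid]))
            )
        ]

    curves = IncidenceCurves.from_first_dates(_clean(exp_firsts), _clean(out_firsts), window)
    nesr = null_effect_sequence_ratio(curves, max_gap, restricted=restricted_nesr)

    if n1 >= 1 and n2 >= 1 and np.isfinite(csr) and np.isfinite(nesr) and nesr > 0:
        asr = adjusted_sequence_ratio(csr, nesr)
        ci_low, ci_high = sequence_ratio_ci(n1, n2, nesr, alpha=alpha, method=ci_method)
    else:
        asr = csr / nesr if np.isfinite(nesr) and nesr > 0 else float("nan")
        ci_low = ci_high = None
    return SsaResult(
        n_exposure_first=n1,
        n_outcome_first=n2,
        csr=csr,
        nesr=nesr,
        asr=asr,
        ci_low=ci_low,
        ci_high=ci_high,
        alpha=alpha,
        attrition=attrition,
    )


class SequenceSymmetry:
    """SSA model over exposure prescriptions and clinical-event claims.

    Parameters
    ----------
    exposures : sequence of PrescriptionRecord
        Dispensings of the drug class under study.
    events : sequence of ClinicalEventRecord
        Diagnosis and procedure claims defining the outcome.
    window : StudyWindow
    route : set of Route, optional
        Restrict exposures to these administration routes.
    max_gap : int
        Largest allowed |first exposure - first outcome| in days (inclusive).
    """

    def __init__(
        self,
        exposures: Sequence[PrescriptionRecord],
        events: Sequence[ClinicalEventRecord],
        window: StudyWindow,
        route: set[Route] | None = None,
        max_gap: int = 90,
    ):
        self.exposures = list(exposures)
        self.events = list(events)
        self.window = window
        self.route = route
        self.max_gap = max_gap

    def fit(
        self,
        alpha: float = 0.05,
        restricted_nesr: bool = True,
        ci_method: str = "clopper_pearson",
    ) -> "SequenceSymmetryResults":
        res = run_ssa(
            self.exposures,
            self.events,
            self.window,
            route_filter=self.route,
            max_gap=self.max_gap,
            alpha=alpha,
            restricted_nesr=restricted_nesr,
            ci_method=ci_method,
        )
        return SequenceSymmetryResults(self, res)


class SequenceSymmetryResults:
    """Fitted SSA: counts, ratios, interval and the attrition audit trail."""

    def __init__(self, model: SequenceSymmetry, result: SsaResult):
        self.model = model
        self._result = result

    @property
    def result(self) -> SsaResult:
        return self._result

    n_exposure_first = property(lambda self: self._result.n_exposure_first)
    n_outcome_first = property(lambda self: self._result.n_outcome_first)
    csr = property(lambda self: self._result.csr)
    nesr = property(lambda self: self._result.nesr)
    asr = property(lambda self: self._result.asr)
    ci_low = property(lambda self: self._result.ci_low)
    ci_high = property(lambda self: self._result.ci_high)
    attrition = property(lambda self: self._result.attrition)

    def summary(self) -> str:
        r = self._result
        conf = f"{100 * (1 - r.alpha):.0f}%"
        ci = (
            f"[{r.ci_low:.3f}, {r.ci_high:.3f}]"
            if r.ci_low is not None
            else "undefined"
        )
        att = r.attrition
        lines = [
            "Sequence Symmetry Analysis",
            "=" * 50,
            f"Max gap: {self.model.max_gap} d   Routes: "
            + (", ".join(sorted(x.value for x in self.model.route)) if self.model.route else "all"),
            f"Patients with exposure:  {att['patients_with_exposure']}",
            f"Patients with outcome:   {att['patients_with_outcome']}",
            f"With both events:        {att['patients_with_both']}",
            f"  excluded, run-in:      {att['excluded_run_in']}",
            f"  excluded, same date:   {att['excluded_same_date']}",
            f"  excluded, gap > {self.model.max_gap:>3}:   {att['excluded_gap']}",
            f"Analyzed pairs:          {att['analyzed']}",
            "-" * 50,
            f"Exposure first (n1):     {r.n_exposure_first}",
            f"Outcome first (n2):      {r.n_outcome_first}",
            f"CSR:                     {r.csr:.4f}",
            f"NESR:                    {r.nesr:.4f}",
            f"ASR:                     {r.asr:.4f}   {conf} CI {ci}",
        ]
        return "\n".join(lines)

    def reversed(self) -> "SsaResult":
        """The analysis with exposure and outcome roles swapped (csr -> 1/csr)."""
        r = self._result
        return replace(
            r,
            n_exposure_first=r.n_outcome_first,
            n_outcome_first=r.n_exposure_first,
            csr=1.0 / r.csr if r.csr not in (0.0,) else float("inf"),
            nesr=1.0 / r.nesr,
            asr=1.0 / r.asr,
            ci_low=1.0 / r.ci_high if r.ci_high else None,
            ci_high=1.0 / r.ci_low if r.ci_low else None,
        )
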