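"""Synthetic longitudinal claims with known, controllable structure.

Real nationwide claims are access-restricted, so every analysis stage here
is exercised against generated data whose ground truth is known: a
prescription-renewal stream per patient with an overuse sub-population
whose monthly intake is inflated by a chosen factor, and an
exposure/outcome event-pair process with a chosen calendar trend in drug
initiation and a chosen multiplicative effect of exposure on the outcome
hazard during a fixed risk window.

Randomness is day-resolution Bernoulli / monthly Poisson with one root seed
and a deterministic per-patient substream, so adding patients never
reshuffles earlier ones and identical configs reproduce byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .dates import month_from_index, month_index, month_key, window_length_days
from .equivalence import DoseEntry, DoseEquivalenceTable
from .records import ClinicalEventRecord, EventKind, PrescriptionRecord, Route, StudyWindow


def default_study_window() -> StudyWindow:
    """August 2010 data start with an eight-month run-in, analysis to March 2016."""
    return StudyWindow(
        data_start=date(2010, 8, 1),
        run_in_end=date(2011, 3, 31),
        analysis_start=date(2011, 4, 1),
        analysis_end=date(2016, 3, 31),
    )


def seven_cohort_window() -> StudyWindow:
    """Same run-in, analysis through March 2018: seven fiscal years of first dates."""
    return StudyWindow(
        data_start=date(2010, 8, 1),
        run_in_end=date(2011, 3, 31),
        analysis_start=date(2011, 4, 1),
        analysis_end=date(2018, 3, 31),
    )


@dataclass(frozen=True)
class IngredientSpec:
    """One drug in the simulated class: sampling weight and standard doses."""

    ingredient: str
    weight: float
    single_dose_mg: float
    max_daily_dose_mg: float
    days_supplied: int = 10
    drug_code: str = ""
    route: Route = Route.SYSTEMIC


def triptan_ingredients() -> tuple[IngredientSpec, ...]:
    """A migraine-drug class mix with clinically typical Japanese doses.

    Sumatriptan succinate (50 mg single / 100 mg max daily) is the
    equivalence reference; each dispensing covers ten intake days at one
    single dose per day.
    """
    return (
        IngredientSpec("sumatriptan succinate", 0.35, 50.0, 100.0, drug_code="TRP-SMT"),
        IngredientSpec("eletriptan hydrobromide", 0.20, 20.0, 40.0, drug_code="TRP-ELE"),
        IngredientSpec("zolmitriptan", 0.15, 2.5, 10.0, drug_code="TRP-ZOL"),
        IngredientSpec("rizatriptan benzoate", 0.20, 10.0, 20.0, drug_code="TRP-RIZ"),
        IngredientSpec("naratriptan hydrochloride", 0.10, 2.5, 5.0, drug_code="TRP-NAR"),
    )


def triptan_dose_table() -> DoseEquivalenceTable:
    entries = [
        DoseEntry(s.ingredient, s.single_dose_mg, s.max_daily_dose_mg)
        for s in triptan_ingredients()
    ]
    return DoseEquivalenceTable(entries, reference="sumatriptan succinate")


@dataclass(frozen=True)
class UtilizationSimConfig:
    """Population parameters for the prescription-renewal generator.

    ``rx_rate_per_month`` is the expected dispensings per month for a
    typical patient; overusers (an ``overuse_fraction`` share of the
    population, drawn per patient) have that rate multiplied by
    ``overuse_intensity``, inflating their monthly equivalent dose by the
    same factor in expectation.
    """

    n_patients: int = 1000
    window: StudyWindow = field(default_factory=default_study_window)
    ingredients: tuple[IngredientSpec, ...] = field(default_factory=triptan_ingredients)
    rx_rate_per_month: float = 0.6
    overuse_fraction: float = 0.05
    overuse_intensity: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overuse_fraction <= 1):
            raise ValueError("overuse_fraction must lie in [0, 1]")
        if self.rx_rate_per_month <= 0 or self.overuse_intensity <= 0:
            raise ValueError("rates must be > 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _patient_rng(root_seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(patient_index,)))


def _month_span(window: StudyWindow) -> list[tuple[date, date]]:
    """(first_day, last_day) of each calendar month intersecting the data window."""
    lo = month_index(month_key(window.data_start))
    hi = month_index(month_key(window.analysis_end))
    spans = []
    for i in range(lo, hi + 1):
        y, m = month_from_index(i)
        first = max(date(y, m, 1), window.data_start)
        last_idx = month_from_index(i + 1)
        last = min(date(last_idx[0], last_idx[1], 1) - timedelta(days=1), window.analysis_end)
        spans.append((first, last))
    return spans


def overuse_flags(cfg: UtilizationSimConfig) -> np.ndarray:
    """Ground-truth overuse assignment, patient by patient (boolean array)."""
    return np.array(
        [
            _patient_rng(cfg.rng_seed, i).random() < cfg.overuse_fraction
            for i in range(cfg.n_patients)
        ]
    )


def simulate_prescriptions(cfg: UtilizationSimConfig) -> list[PrescriptionRecord]:
    """Prescription streams for the utilization studies.

    Monthly dispensing counts are Poisson at the patient's rate; each
    dispensing picks an ingredient by weight and a uniform day within the
    month (clipped to the data window).
    """
    spans = _month_span(cfg.window)
    weights = np.array([s.weight for s in cfg.ingredients], dtype=float)
    weights = weights / weights.sum()
    records: list[PrescriptionRecord] = []
    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.rng_seed, i)
        heavy = rng.random() < cfg.overuse_fraction  # first draw: ground-truth flag
        rate = cfg.rx_rate_per_month * (cfg.overuse_intensity if heavy else 1.0)
        pid = f"P{i:06d}"
        counts = rng.poisson(rate, size=len(spans))
        for (first, last), k in zip(spans, counts):
            if k == 0:
                continue
            span_days = (last - first).days + 1
            for idx, off in zip(
                rng.choice(len(cfg.ingredients), size=k, p=weights),
                rng.integers(0, span_days, size=k),
            ):
                spec = cfg.ingredients[idx]
                records.append(
                    PrescriptionRecord(
                        patient_id=pid,
                        drug_code=spec.drug_code or spec.ingredient,
                        ingredient=spec.ingredient,
                        route=spec.route,
                        dispense_date=first + timedelta(days=int(off)),
                        days_supplied=spec.days_supplied,
                        daily_dose=spec.single_dose_mg,
                    )
                )
    return records


@dataclass(frozen=True)
class SsaSimConfig:
    """Exposure/outcome pair generator for the sequence-symmetry stage.

    Exposure initiation is a daily Bernoulli with probability ramping
    linearly from ``exposure_p_start`` to ``exposure_p_end`` across the data
    window (equal values give a constant curve).  Outcomes occur daily at
    ``outcome_daily_p``, multiplied by ``effect`` on the ``risk_window_days``
    days after the first exposure.  Every outcome day emits a diagnosis and
    a procedure claim on the same date, so the diagnosis-plus-procedure
    same-month outcome definition fires.  All exposure days are emitted as
    prescriptions; only the first matters downstream.
    """

    n_patients: int = 2000
    window: StudyWindow = field(
        default_factory=lambda: StudyWindow(
            date(2010, 8, 1), date(2011, 3, 31), date(2011, 4, 1), date(2013, 3, 31)
        )
    )
    exposure_p_start: float = 0.001
    exposure_p_end: float = 0.001
    outcome_daily_p: float = 0.0025
    effect: float = 1.0
    risk_window_days: int = 30
    route: Route = Route.SYSTEMIC
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.exposure_p_start, self.exposure_p_end, self.outcome_daily_p):
            if not (0 <= p <= 1):
                raise ValueError("daily probabilities must lie in [0, 1]")
        if self.effect <= 0:
            raise ValueError("effect must be > 0")
        if self.risk_window_days < 1:
            raise ValueError("risk_window_days must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def linear_trend_config(**overrides) -> SsaSimConfig:
    """A strong-trend null scenario: steeply rising initiation, no true effect.

    Drug initiation ramps from 0 to 0.006 per day across a three-year
    analysis window while the first-outcome curve declines through
    depletion, which biases the crude sequence ratio well below 1; the
    null-effect sequence ratio exists to absorb exactly this.
    """
    base = dict(
        window=StudyWindow(
            date(2010, 8, 1), date(2011, 3, 31), date(2011, 4, 1), date(2014, 3, 31)
        ),
        exposure_p_start=0.0,
        exposure_p_end=0.006,
        outcome_daily_p=0.005,
        effect=1.0,
    )
    base.update(overrides)
    return SsaSimConfig(**base)


def simulate_exposure_outcome(
    cfg: SsaSimConfig,
) -> tuple[list[PrescriptionRecord], list[ClinicalEventRecord]]:
    """Draw per-patient exposure and outcome event streams."""
    w = cfg.window
    n_days = window_length_days(w.data_start, w.analysis_end)
    p_exp = np.linspace(cfg.exposure_p_start, cfg.exposure_p_end, n_days)
    exposures: list[PrescriptionRecord] = []
    events: list[ClinicalEventRecord] = []
    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.rng_seed, i)
        pid = f"S{i:06d}"
        exp_days = np.flatnonzero(rng.random(n_days) < p_exp)
        for d in exp_days:
            exposures.append(
                PrescriptionRecord(
                    patient_id=pid,
                    drug_code="ABX-FQ",
                    ingredient="fluoroquinolone",
                    route=cfg.route,
                    dispense_date=w.data_start + timedelta(days=int(d)),
                    days_supplied=7,
                    daily_dose=500.0,
                )
            )
        p_out = np.full(n_days, cfg.outcome_daily_p)
        if exp_days.size and cfg.effect != 1.0:
            first = int(exp_days[0])
            hi = min(first + cfg.risk_window_days + 1, n_days)
            p_out[first + 1 : hi] = np.minimum(1.0, cfg.outcome_daily_p * cfg.effect)
        out_days = np.flatnonzero(rng.random(n_days) < p_out)
        for d in out_days:
            day = w.data_start + timedelta(days=int(d))
            events.append(ClinicalEventRecord(pid, "DX-RD", day, EventKind.DIAGNOSIS))
            events.append(ClinicalEventRecord(pid, "PX-RD-SURG", day, EventKind.PROCEDURE))
    return exposures, events
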