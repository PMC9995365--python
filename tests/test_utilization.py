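import random
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from claimslab import (
    EXCLUDED,
    CumulativeDoseStudy,
    DurationStudy,
    MonthlyDoseSeries,
    OveruseCriterion,
    OveruseStatus,
    OveruseStudy,
    assign_subcohorts,
    classify_overuse,
    cumulative_dose,
    frequency_distribution,
    merged_prescription_days,
    monthly_equivalent_dose,
    summarize,
    triptan_dose_table,
)
from claimslab.dates import month_from_index, month_index
from claimslab.equivalence import UnknownIngredientError

# ---------------------------------------------------------------------------
# monthly equivalent dose


def test_reference_ingredient_converts_one_to_one(dose_table, rx):
    series = monthly_equivalent_dose([rx(d="2012-03-05", days=10, dose=50.0)], dose_table, "single_dose")
    assert series.totals == {(2012, 3): 500.0}


def test_ratio_scaling_single_dose_basis(dose_table, rx):
    # 200 mg of a 20 mg-single-dose drug equals 500 mg of the 50 mg reference
    rec = rx(d="2012-03-05", days=10, dose=20.0, ingredient="eletriptan hydrobromide")
    series = monthly_equivalent_dose([rec], dose_table, "single_dose")
    assert series.totals[(2012, 3)] == pytest.approx(500.0)


def test_months_partition_without_bleed_over(dose_table, rx):
    recs = [rx(d="2012-03-05"), rx(d="2012-05-20")]
    series = monthly_equivalent_dose(recs, dose_table, "single_dose")
    assert series.totals == {(2012, 3): 500.0, (2012, 4): 0.0, (2012, 5): 500.0}
    assert series.rx_months == {(2012, 3), (2012, 5)}


def test_unknown_ingredient_named(dose_table, rx):
    with pytest.raises(UnknownIngredientError, match="ergotamine"):
        monthly_equivalent_dose([rx(ingredient="ergotamine")], dose_table, "single_dose")


@given(st.permutations(range(6)), st.floats(min_value=0.25, max_value=4.0))
def test_reorder_invariance_and_dose_homogeneity(perm, scale):
    table = triptan_dose_table()
    from claimslab import PrescriptionRecord, Route

    base = [
        PrescriptionRecord(
            "P1", "c", "sumatriptan succinate", Route.SYSTEMIC,
            date(2012, 1, 1) + timedelta(days=20 * i), 5, 10.0 * (i + 1),
        )
        for i in range(6)
    ]
    ref = monthly_equivalent_dose(base, table, "single_dose")
    shuffled = monthly_equivalent_dose([base[i] for i in perm], table, "single_dose")
    assert shuffled.totals == ref.totals
    scaled = [
        PrescriptionRecord(r.patient_id, r.drug_code, r.ingredient, r.route,
                           r.dispense_date, r.days_supplied, r.daily_dose * scale)
        for r in base
    ]
    out = monthly_equivalent_dose(scaled, table, "single_dose")
    for k in ref.totals:
        assert out.totals[k] == pytest.approx(scale * ref.totals[k])


# ---------------------------------------------------------------------------
# overuse classification


def _series(totals, start=(2012, 1), pid="P1"):
    i0 = month_index(start)
    months = {month_from_index(i0 + i): float(t) for i, t in enumerate(totals)}
    rx_months = frozenset(k for k, v in months.items() if v > 0)
    return MonthlyDoseSeries(patient_id=pid, totals=months, rx_months=rx_months)


def test_four_consecutive_months_fires(dose_table):
    # reference single dose 50 mg -> monthly threshold 500 mg
    a = classify_overuse(_series([600, 600, 600, 600]), dose_table, "single_dose")
    assert a.status is OveruseStatus.SUSPECTED_OVERUSE
    assert a.triggering_criterion is OveruseCriterion.CONSECUTIVE_MONTHS
    assert a.trigger_month == (2012, 1)
    assert a.multiplier_x is None


def test_bulk_multiple_with_refill_fires(dose_table):
    a = classify_overuse(_series([2100, 0, 0, 60]), dose_table, "single_dose")
    assert a.triggering_criterion is OveruseCriterion.MULTIPLE_WITH_REFILL
    assert a.multiplier_x == 4
    assert a.trigger_month == (2012, 1)


def test_three_months_do_not_fire(dose_table):
    a = classify_overuse(_series([600, 600, 600]), dose_table, "single_dose")
    assert a.status is OveruseStatus.NONE
    assert a.triggering_criterion is OveruseCriterion.NOT_APPLICABLE


def test_exact_multiple_is_not_exceeded(dose_table):
    # 2000 mg equals 4 x 500 exactly; "exceeded" is strict, and X=3 < 4
    a = classify_overuse(_series([2000, 0, 0, 60]), dose_table, "single_dose")
    assert a.status is OveruseStatus.NONE


def test_refill_outside_x_months_does_not_fire(dose_table):
    # X = 4, refill in month m+5 is too late
    a = classify_overuse(_series([2100, 0, 0, 0, 0, 60]), dose_table, "single_dose")
    assert a.status is OveruseStatus.NONE


def test_max_daily_basis_reports_overuse_status(dose_table):
    # threshold becomes 10 x 100 mg = 1000 mg
    a = classify_overuse(_series([1100, 1100, 1100, 1100]), dose_table, "max_daily_dose")
    assert a.status is OveruseStatus.OVERUSE
    b = classify_overuse(_series([600, 600, 600, 600]), dose_table, "max_daily_dose")
    assert b.status is OveruseStatus.NONE


def test_gap_breaks_consecutive_run(dose_table):
    a = classify_overuse(_series([600, 600, 0, 600, 600]), dose_table, "single_dose")
    assert a.status is OveruseStatus.NONE


def _brute_force_overuse(series, threshold):
    """Exhaustive re-derivation: every 4-month window, every X >= 4."""
    months = series.months()
    totals = [series.totals[m] for m in months]
    rx_idx = {month_index(m) for m in series.rx_months}
    c1 = None
    for i in range(len(months) - 3):
        if all(t > threshold for t in totals[i : i + 4]):
            c1 = months[i]
            break
    c2 = None
    x_report = None
    for i, m in enumerate(months):
        xs = [x for x in range(4, int(totals[i] / threshold) + 2) if totals[i] > x * threshold]
        if not xs:
            continue
        x = max(xs)
        mi = month_index(m)
        if any(j in rx_idx for j in range(mi + 1, mi + x + 1)):
            c2 = m
            x_report = x
            break
    if c1 is not None and (c2 is None or month_index(c1) <= month_index(c2)):
        return OveruseCriterion.CONSECUTIVE_MONTHS, c1, None
    if c2 is not None:
        return OveruseCriterion.MULTIPLE_WITH_REFILL, c2, x_report
    return OveruseCriterion.NOT_APPLICABLE, None, None


def test_classifier_matches_exhaustive_enumeration(dose_table):
    rng = random.Random(7)
    threshold = 500.0
    for _ in range(1000):
        n = rng.randrange(1, 25)
        totals = [
            rng.choice([0, 0, 120, 480, 501, 600, 1400, 2001, 2100, 2600, 5100])
            for _ in range(n)
        ]
        series = _series(totals, start=(2011, rng.randrange(1, 13)))
        got = classify_overuse(series, dose_table, "single_dose")
        crit, month, x = _brute_force_overuse(series, threshold)
        assert got.triggering_criterion is crit
        assert got.trigger_month == month
        assert got.multiplier_x == x


# ---------------------------------------------------------------------------
# cumulative dose and merged days


def test_cumulative_dose_examples(rx):
    assert cumulative_dose([]) == 0.0
    assert cumulative_dose([rx(days=670, dose=160.0)]) == 107_200.0
    assert cumulative_dose([rx(days=10, dose=80.0), rx(days=5, dose=40.0)]) == 1_000.0


def test_merged_days_overlap_counted_once(rx):
    recs = [rx(d="2013-01-01", days=30), rx(d="2013-01-15", days=30)]
    assert merged_prescription_days(recs) == 44  # union covers Jan 1 - Feb 13


def test_merged_days_disjoint_additive_and_idempotent(rx):
    a = rx(d="2013-01-01", days=30)
    b = rx(d="2013-06-01", days=30)
    assert merged_prescription_days([a, b]) == 60
    assert merged_prescription_days([a, a]) == 30
    assert merged_prescription_days([]) == 0


def test_merged_days_adjacent_intervals_chain(rx):
    # supply ending Jan 30 followed by supply starting Jan 31: contiguous
    recs = [rx(d="2013-01-01", days=30), rx(d="2013-01-31", days=10)]
    assert merged_prescription_days(recs) == 40


def test_merged_days_matches_day_set_cardinality(rx):
    """Interval-merge algorithm vs the brute-force union of explicit day sets."""
    rng = random.Random(11)
    base = date(2012, 1, 1)
    for _ in range(1000):
        recs = [
            rx(d=(base + timedelta(days=rng.randrange(0, 400))).isoformat(),
               days=rng.randrange(1, 60))
            for _ in range(rng.randrange(1, 21))
        ]
        day_set = set()
        for r in recs:
            start = r.dispense_date.toordinal()
            day_set.update(range(start, start + r.days_supplied))
        assert merged_prescription_days(recs) == len(day_set)


@given(
    st.lists(
        st.tuples(st.integers(min_value=0, max_value=300), st.integers(min_value=1, max_value=45)),
        min_size=1,
        max_size=15,
    )
)
def test_merged_days_bounds(intervals):
    from claimslab import PrescriptionRecord, Route

    base = date(2012, 1, 1)
    recs = [
        PrescriptionRecord("P1", "c", "i", Route.SYSTEMIC, base + timedelta(days=off), days, 1.0)
        for off, days in intervals
    ]
    merged = merged_prescription_days(recs)
    assert max(r.days_supplied for r in recs) <= merged <= sum(r.days_supplied for r in recs)


# ---------------------------------------------------------------------------
# sub-cohorts


def test_run_in_first_dates_excluded(window):
    cohorts = assign_subcohorts({"A": date(2010, 9, 15)}, window)
    assert cohorts["A"] == EXCLUDED


def test_boundary_day_starts_cohort(window):
    assert assign_subcohorts({"A": date(2011, 4, 1)}, window)["A"] == 2011


def test_seven_fiscal_years_of_first_dates():
    from claimslab import seven_cohort_window

    w = seven_cohort_window()
    firsts = {}
    d = w.analysis_start
    i = 0
    while d <= w.analysis_end:
        firsts[f"P{i}"] = d
        d += timedelta(days=30)
        i += 1
    labels = set(assign_subcohorts(firsts, w).values()) - {EXCLUDED}
    assert labels == set(range(2011, 2018))
    assert len(labels) == 7


def test_first_date_outside_window_is_error(window):
    with pytest.raises(ValueError):
        assign_subcohorts({"A": date(2009, 1, 1)}, window)


def test_cohort_labels_confined_to_analysis_span(window):
    rng = random.Random(3)
    span = (window.analysis_end - window.data_start).days
    firsts = {
        f"P{i}": window.data_start + timedelta(days=rng.randrange(0, span + 1))
        for i in range(300)
    }
    # post-run-in first dates start 2011-04-01, so labels span fiscal 2011-2015
    fy_lo, fy_hi = 2011, 2015
    for label in assign_subcohorts(firsts, window).values():
        if label != EXCLUDED:
            assert fy_lo <= label <= fy_hi


# ---------------------------------------------------------------------------
# summary statistics and histogram


def test_summarize_order_statistics():
    s = summarize([1, 2, 3, 4, 5])
    assert (s.median, s.q1, s.q3, s.min, s.max) == (3, 2, 4, 1, 5)
    assert s.mean == 3 and s.n == 5
    assert s.sd == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))


def test_summarize_constant_and_empty():
    s = summarize([7.0] * 4)
    assert s.sd == 0.0 and s.min == s.max == s.median == 7.0
    with pytest.raises(ValueError):
        summarize([])


def test_summarize_extremes_are_endpoints():
    s = summarize([40, 33_600, 360_000])
    assert s.min == 40 and s.max == 360_000
    assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


def test_frequency_distribution_basic_bins():
    bins = frequency_distribution([5, 15], 10)
    assert [(b.lower, b.upper, b.count) for b in bins] == [(0, 10, 1), (10, 20, 1)]


def test_frequency_distribution_counts_conserved_with_interior_zeros():
    rng = random.Random(5)
    values = [rng.uniform(0, 90_000) for _ in range(500)]
    bins = frequency_distribution(values, 7_000)
    assert sum(b.count for b in bins) == len(values)
    uppers = [b.upper for b in bins]
    assert uppers == sorted(uppers)
    # bins tile the occupied range with no holes
    for left, right in zip(bins, bins[1:]):
        assert left.upper == right.lower


def test_max_dose_falls_in_printed_band():
    # 160 mg/day over the full 670-day span lands in the 100,000-110,000 mg bin
    bins = frequency_distribution([107_200.0], 10_000)
    assert len(bins) == 1
    assert (bins[0].lower, bins[0].upper) == (100_000, 110_000)


def test_frequency_distribution_rejects_bad_width():
    with pytest.raises(ValueError):
        frequency_distribution([1.0], 0)


# ---------------------------------------------------------------------------
# model classes


def test_overuse_study_flags_heavy_patient(dose_table, rx):
    heavy = [rx(pid="H", d=f"2012-{m:02d}-10", days=12, dose=50.0) for m in (1, 2, 3, 4)]
    light = [rx(pid="L", d="2012-01-10", days=5, dose=50.0)]
    res = OveruseStudy(heavy + light, dose_table).fit(basis="single_dose")
    by_pid = {a.patient_id: a for a in res.assessments}
    assert by_pid["H"].status is OveruseStatus.SUSPECTED_OVERUSE
    assert by_pid["L"].status is OveruseStatus.NONE
    assert res.n_patients == 2 and res.n_flagged == 1
    assert "suspected overuse" in res.summary()


def test_duration_study_cohort_table(window, rx):
    recs = [
        rx(pid="A", d="2011-06-01", days=30, dose=500.0),
        rx(pid="A", d="2011-06-15", days=30, dose=500.0),  # overlap merged
        rx(pid="B", d="2010-10-01", days=30, dose=500.0),  # run-in entry
    ]
    res = DurationStudy(recs, window).fit()
    a = next(s for s in res.summaries if s.patient_id == "A")
    assert a.cumulative_days == 44
    assert a.cumulative_dose == pytest.approx(30_000.0)
    assert a.daily_dose_per_patient == pytest.approx(30_000.0 / 44)
    assert a.fiscal_cohort == 2011
    assert res.n_excluded == 1
    assert res.cohorts() == [2011]


def test_cumulative_dose_study_histogram_and_stats(rx):
    recs = [rx(pid="A", days=670, dose=160.0), rx(pid="B", days=10, dose=4.0)]
    res = CumulativeDoseStudy(recs).fit(bin_width=10_000)
    assert res.doses == {"A": 107_200.0, "B": 40.0}
    assert res.stats.max == 107_200.0 and res.stats.min == 40.0
    assert res.histogram[-1].count == 1 and res.histogram[-1].lower == 100_000
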