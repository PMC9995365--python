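# Methods

## Data model

All analyses run over two per-patient event streams held at day resolution:
prescription records (patient, drug code, ingredient, administration route,
dispense date, days supplied ≥ 1, daily dose > 0 mg) and clinical-event
records (patient, code, date, diagnosis or procedure). Month-level logic is
always derived from stored dates via calendar month keys, never by
truncating the data. Day counts are inclusive of both endpoints
(June 1 2014 – March 31 2016 counts 670 days). The Japanese fiscal year
labels April 1 of year *y* through March 31 of *y*+1 as *y*.

A study calendar is four dates: `data_start ≤ run_in_end < analysis_start ≤
analysis_end`. The run-in span `[data_start, run_in_end]` (default
2010-08-01 – 2011-03-31) is observed only to establish incidence: a first
event inside it disqualifies the patient from incident-user analyses.

Input tables are comma- or tab-separated text with a header, ISO-8601
dates, and an optional column-mapping schema, since claims exports do not
share a layout. Duplicate rows are kept by default — repeat claims are
legitimate — with deduplication behind a flag. Invalid rows are collected
and reported with 1-based data-row indices rather than failing on the
first.

## Dose equivalence and overuse phenotyping

Doses of different ingredients in a class are expressed in milligrams of a
reference ingredient by ratio scaling: equivalent mg = raw mg × (reference
basis dose ÷ ingredient basis dose), where the basis is either the standard
single dose or the maximum daily dose. Ratio scaling is the standard
dose-equivalence construction; the basis is an explicit parameter because
the two overuse definitions below differ only in it. Reference doses are
configuration inputs, never hard-coded; the bundled synthetic class uses
clinically typical values (sumatriptan succinate 50/100 mg as reference,
eletriptan 20/40, zolmitriptan 2.5/10, rizatriptan 10/20, naratriptan
2.5/5).

The monthly series assigns each prescription's total (daily dose × days
supplied, converted) wholly to its dispense month and zero-fills months
between the patient's first and last prescription months, so
"consecutive months" is well defined.

With T = 10 × (reference basis dose), a patient is flagged when either

1. the monthly equivalent total strictly exceeds T in ≥ 4 consecutive
   calendar months (trigger month = first month of the earliest such run), or
2. some month m strictly exceeds X·T, where X is the largest integer ≥ 4
   satisfying the bound, and any prescription occurs in calendar months
   m+1 … m+X (the refill evidences that the bulk supply was consumed).

"Exceeds" is strict in both criteria; an exact multiple does not qualify.
The earliest triggering month is reported, criterion 1 winning ties.
Whether the refill window should be calendar months or 30-day blocks is
not determinate from the phenotype's description; calendar months were
chosen for consistency with the monthly aggregation, and the choice is
isolated in one place. The single-dose basis labels patients
"suspected overuse", the max-daily-dose basis "overuse"; the two
definitions run independently.

## Cumulative dose, merged days, sub-cohorts

Cumulative dose is the plain sum Σ daily dose × days supplied — dose is
additive, so overlapping supplies are *not* merged. Treated time is the
opposite: the size of the union of supply intervals
`[dispense_date, dispense_date + days_supplied − 1]`, overlap days counted
once (sorted interval merge, checked against the explicit day-set union).
Per-patient daily dose = cumulative dose / merged days.

Summary statistics use the sample SD (n−1; reported as 0 for n = 1) and
linear-interpolation quartiles (numpy's default), stated here so tabulated
outputs are reproducible bit for bit. Frequency distributions use
half-open bins [k·w, (k+1)·w) with interior empty bins emitted; the default
width of 10,000 mg matches the granularity at which cumulative-dose bands
are conventionally reported, and 160 mg/day over the full 670-day span
(107,200 mg) lands in the 100,000–110,000 mg bin.

Fiscal sub-cohorts label each patient by the fiscal year of their first
prescription; first dates in the run-in span map to an excluded marker, and
a first date outside the data window is an error because it contradicts
the premise that the minimum was taken over the full window. First dates
spanning April 2011 – March 2018 yield exactly seven cohorts.

## Sequence symmetry analysis

The outcome is an event qualified by ≥ 1 diagnosis claim and ≥ 1 procedure
claim in the same calendar month; the month's outcome date is its earliest
procedure date (the procedure — the surgery — is the event of interest, so
it anchors the date; this is a documented convention, not an inference),
and the patient's outcome is the earliest qualifying date.

Pairing takes each patient's first-ever exposure and first-ever outcome,
then excludes: either date in the run-in span; identical dates (order
undefined — and such pairs would otherwise inflate neither count
consistently); gap > `max_gap` days. "Within 90 days" is read as closed,
gap ≤ 90. Every exclusion is a named attrition counter and the counters
provably conserve the patients-with-both total.

CSR = n₁/n₂. The NESR is computed from the marginal daily incidence curves
of the post-run-in population (all first exposure dates and all first
outcome dates inside the analysis window, before the gap restriction), as

A = Σ_t e_t Σ_{t<s≤t+g} o_s,  B = Σ_t e_t Σ_{t−g≤s<t} o_s,  NESR = A/B,

i.e. the expected order split when an exposure day and an outcome day are
drawn independently from the marginals under the *same* gap restriction and
same-day exclusion as the cohort. The waiting-time-restricted form is the
default because the null expectation should match the cohort construction;
the classical unrestricted form (all ordered pairs of distinct days) is
available via `restricted=False`. Both are implemented with cumulative
sums and verified against exhaustive ordered-pair enumeration. Swapping
the exposure and outcome roles maps CSR → 1/CSR and NESR → 1/NESR exactly.

ASR = CSR / NESR. The interval treats n₁ as binomial(n₁+n₂, p): an exact
Clopper–Pearson interval on p (beta quantiles; independently checked by
direct inversion of the binomial CDF), transformed by r = p/(1−p) and
divided by the NESR. Clopper–Pearson was chosen for validity at the small
counts SSA routinely produces; a Wilson score variant is available via
`method="wilson"`. Degenerate cases do not crash: n₂ = 0 flags an infinite
CSR with an undefined CI, an empty cohort returns a structured empty
result.

## Synthetic claims generator

The generator emulates exactly the statistical structure the four analyses
assume, with one root seed and per-patient substreams derived via
`SeedSequence(root, spawn_key=(patient,))`, so output is byte-reproducible
and adding patients never reshuffles earlier ones.

*Utilization stream.* Monthly dispensing counts are Poisson at 0.6
prescriptions/month — an intermittent-therapy rate typical of acute
migraine treatment — over the 2010-08 – 2016-03 window; each dispensing
draws an ingredient by mixture weight, covers 10 intake days at one single
dose per day, and lands uniformly in its month. A per-patient draw marks
an overuse sub-population (default fraction 0.05, matching the mid-single-
digit prevalence such screens report) whose monthly rate is inflated
five-fold, pushing expected monthly equivalents well past the 10-dose
threshold. The ground-truth flags are recomputable (`overuse_flags`), so
tests can compare detected against planted prevalence.

*Exposure/outcome stream.* Day-resolution Bernoulli draws (simple,
adequate at desk scale, and trivially enumerable by oracles): exposure
initiation probability ramps linearly across the data window (constant and
linear shapes only — sufficient to demonstrate trend-induced CSR bias);
all exposure days are emitted as prescriptions so first-occurrence
extraction is exercised, but only the first drives the outcome model.
Outcomes occur daily at a baseline probability, multiplied by `effect` on
the `risk_window_days` (default 30) days strictly after the first
exposure; each outcome day emits a same-date diagnosis and procedure claim
so the same-month outcome definition fires. Defaults: 2,000 patients, a
two-year analysis window, constant initiation at 0.001/day, baseline
outcome 0.0025/day.

`linear_trend_config` freezes the strong-trend null scenario used for
calibration checks: a three-year analysis window, initiation ramping from
0 to 0.006/day, baseline outcome 0.005/day, effect 1. The steep ramp
against the depletion-driven decline of the first-outcome curve drives the
NESR to ≈ 0.78, far enough from 1 that the uncorrected CSR interval
visibly loses coverage (≈ 75–80% over 200 replicates) while the ASR
interval holds ≈ 95%. The scenario's parameters were set by design
analysis of that bias-versus-interval-width trade-off, then frozen.

What the generator does **not** emulate: comorbidity and indication
confounding, dose titration, real drug-code dictionaries, seasonal or
non-linear calendar patterns, month-resolution claim dates, or informative
censoring. Passing tests therefore demonstrate the correctness of the
algorithms and the trend-adjustment mechanism, not robustness to the
confounding structure of real claims.

## Problem sizes and runtime

The test suite and the acceptance script use 1,000 randomized patients for
the interval-merge oracle, 1,000 random monthly series (length ≤ 24) for
the overuse oracle, 300 random curve pairs (windows ≤ 30 days) for the
NESR oracle, 200 × 2,000 patients for the null-calibration coverage run,
and 5,000 patients for effect recovery — sizes at which the Monte-Carlo
bounds asserted are stable while a full run stays around a minute on one
CPU.

## Known limitations

- The NESR construction assumes independence of the two marginal curves
  under the null; a shared confounder that shifts both curves jointly is
  not adjusted for (inherent to the design, not the implementation).
- The overuse criteria operate on dispense-month totals; a supply
  dispensed late in a month but consumed in the next is attributed to the
  dispense month.
- Route stratification filters exposures only; outcomes are not
  route-specific.
- All dates are assumed day-accurate; claims systems that record only the
  month will bias gap-based exclusions.
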