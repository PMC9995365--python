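# claimslab

Drug-utilization and safety-signal analyses over longitudinal prescription
claims, for pharmacoepidemiologists who need nationwide-claims-style study
designs to run — and be testable — at desk scale.

Administrative claims databases record, per patient, a stream of dispensing
events (drug, route, dispense date, daily dose, days supplied) and a stream
of diagnosis/procedure claims. `claimslab` implements four study patterns
over that data model:

1. **Medication-overuse phenotyping.** Each patient's prescriptions are
   converted to a monthly dose series in milligrams of a reference
   ingredient (dose equivalence by the ratio of standard single or maximum
   daily doses) and screened against two criteria: the monthly total
   exceeds 10 reference doses in ≥ 4 consecutive calendar months, or one
   month exceeds X·(10 reference doses) for an integer X ≥ 4 with a further
   prescription within the next X months. The single-dose basis yields a
   "suspected overuse" phenotype; the max-daily-dose basis the stricter
   "overuse".
2. **Cumulative dose per patient**: Σ daily dose × days supplied, with
   summary statistics and a fixed-width frequency distribution.
3. **Prescription duration**: treated days as the union of supply intervals
   (overlap days counted once), per-patient daily dose as cumulative dose /
   merged days, stratified into Japanese fiscal-year sub-cohorts of the
   first prescription date (first dates in the run-in span are excluded as
   non-incident).
4. **Sequence symmetry analysis (SSA)** for signal detection. Among
   patients whose first-ever exposure and first-ever outcome fall within a
   gap of `g` days (default 90), with run-in and same-date exclusions, the
   crude sequence ratio is

   CSR = n₁/n₂, n₁ = # exposure→outcome, n₂ = # outcome→exposure.

   Calendar trends bias the CSR, so it is divided by the null-effect
   sequence ratio computed from the marginal daily incidence curves
   (e_t incident exposures, o_t incident outcomes):

   NESR = A/B, A = Σ_t e_t · Σ_{t<s≤t+g} o_s, B = Σ_t e_t · Σ_{t−g≤s<t} o_s,

   and the adjusted sequence ratio ASR = CSR / NESR ≈ 1 under the null.
   Confidence intervals treat n₁ as binomial(n₁+n₂, p) with an exact
   Clopper–Pearson interval mapped through the odds transform p/(1−p) and
   divided by the NESR (Wilson score available behind a flag).

Because nationwide claims are access-restricted, the package ships a
synthetic claims generator (`claimslab.simulate`) with known ground truth —
an overuse sub-population with inflated monthly intake, linear calendar
trends in drug initiation, and a controllable multiplicative effect of
exposure on the outcome hazard — so every pipeline stage runs end-to-end
with no external data.

## Worked example

```python
from claimslab import (SequenceSymmetry, linear_trend_config,
                       simulate_exposure_outcome)

cfg = linear_trend_config(n_patients=2000, rng_seed=42)   # null: effect = 1
exposures, events = simulate_exposure_outcome(cfg)
print(SequenceSymmetry(exposures, events, cfg.window).fit().summary())
```

```
Sequence Symmetry Analysis
==================================================
Max gap: 90 d   Routes: all
Patients with exposure:  1973
Patients with outcome:   2000
With both events:        1973
  excluded, run-in:      1474
  excluded, same date:   1
  excluded, gap >  90:   388
Analyzed pairs:          110
--------------------------------------------------
Exposure first (n1):     49
Outcome first (n2):      61
CSR:                     0.8033
NESR:                    0.8755
ASR:                     0.9175   95% CI [0.617, 1.359]
```

The scenario has no true exposure→outcome effect, but drug initiation rises
steeply over the study period, so outcome-first pairs dominate and the CSR
sits at 0.80. The NESR computed from the marginal incidence curves predicts
0.88 of that asymmetry from the trend alone; the adjusted ratio is 0.92
with a 95% interval comfortably covering 1 — no spurious signal.

The utilization side works the same way:

```python
from claimslab import (OveruseStudy, UtilizationSimConfig,
                       simulate_prescriptions, triptan_dose_table)

recs = simulate_prescriptions(UtilizationSimConfig(n_patients=500, rng_seed=42))
print(OveruseStudy(recs, triptan_dose_table()).fit(basis="single_dose").summary())
```

```
Overuse phenotyping
==============================================
Dose basis:              single_dose
Patients analysed:       500
Flagged (suspected overuse): 38 (7.60%)
  via consecutive months: 22
  via bulk multiple + refill: 16
```

The generator planted a 5% heavy-intake sub-population (rate inflated
five-fold); the classifier flags them plus a small tail of ordinary
patients who randomly cross the monthly threshold for four straight months.

A `claimslab` command-line tool wraps the same pipelines
(`simulate`, `dus-overuse`, `dus-cumdose`, `dus-duration`, `ssa`) around
YAML/JSON study configs, writing per-patient TSV tables plus JSON reports
with full attrition counters; see `claimslab --help`.

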