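# Methods

## Scope and model

`vitalfuzz` grades a patient's health condition from five simultaneous vital
readings — temperature (°C), heart rate (bpm), SpO₂ (%), systolic blood
pressure (mmHg), blood glucose (mg/dL) — using a Mamdani fuzzy inference
system, and supports that core with crisp range classification, record
cleaning, stream triage, a Beer–Lambert glucose model, a synthetic cohort
generator and a classifier benchmark. Everything is deterministic given the
seeds; there is no fitting or learning inside the inference path.

## Crisp classification and cleaning

The crisp range table assigns each non-negative reading to exactly one label
per vital. Each interval is closed on its printed lower bound and the top
interval is unbounded ("X and above"), so coverage of [0, ∞) is total and
disjoint. Two consequences worth noting:

- Printed integer range ends leave real-valued gaps (glucose Normal ends at
  100, Elevated starts at 101). The closed-lower-bound rule assigns such gap
  values (e.g. 100.5) to the *lower* label. This is a convention, not a
  clinical claim.
- The heart-rate Normal band of 110–155 bpm is far above resting norms for
  adults. It is implemented verbatim as the system's operating definition
  (the monitored population and sensor placement are not ours to re-derive);
  users can override the range table.

Blood pressure is systolic-only: the thresholds (90/120/130) are systolic and
no diastolic channel exists anywhere in the stack.

Cleaning drops records with any missing reading (blank/NaN), any exact-zero
reading (physically impossible for all five vitals), or any reading outside
open plausibility bounds: temperature (25, 45) °C, HR (20, 250) bpm,
SpO₂ (50, 100] %, BP (40, 250) mmHg, glucose (20, 600) mg/dL. The bounds are
configurable; the defaults are deliberately generous so that cleaning removes
sensor artifacts, not pathology. Cleaning is idempotent and order-preserving,
and its report reconciles exactly (input = dropped + retained).

Temperature's canonical unit is °C. Where instruments report °F the CLI flag
`--fahrenheit` converts on ingest; the classification table only reads as
body temperature in °C.

## Membership functions

All membership functions are piecewise-linear trapezoids (triangles are
trapezoids with b = c). Degenerate vertical edges (a = b or c = d) evaluate
to the plateau value at the shared point, making edge plateaus closed — the
Low blood-pressure function (0, 0, 60, 90) is 1 at 0.

Two parameter sets ship:

- **`as_printed`** reproduces the published listing exactly, with two
  documented repairs. (1) The oxygen Worrisome breakpoints arrive as
  (85, 90, 95, 93), violating c ≤ d; the only ordering consistent with the
  stated 90–93 Worrisome range is (85, 90, 93, 95), so c and d are swapped.
  (2) The temperature triangles (0,0,17)/(15,20,25)/(23,30,40) do not cover
  physiologic °C readings and disagree with the crisp table; they are kept
  verbatim (they appear to describe a rescaled axis) and `as_printed` is
  therefore not the default.
- **`range_consistent`** (default) is constructed from the crisp table: a
  label with printed interval [lo, hi] gets the trapezoid
  (lo − s, lo, hi, hi + s) with shoulder width s = 2 units (configurable),
  the first label's left edge degenerate at 0 and the top label's plateau
  unbounded. Each label's plateau then equals its crisp range, so for any
  reading at least 2 units from every boundary the argmax membership label
  equals the crisp label. The 2-unit shoulder is a design choice: wide enough
  to give the gradual transitions fuzzification exists for, narrow enough
  that fuzzy and crisp views rarely disagree.

## Rule base and inference

The rule base is the union of seven expert IF–THEN rules and seven
calibration rows, all with full five-vital crisp antecedents. Three
calibration rows duplicate expert rules (with identical consequents); the
expert rule takes precedence and the base holds 11 distinct rules. Any
antecedent collision with differing consequents is a construction error.

Inference is Mamdani with AND = min and aggregation = max; the published
description names the operators without defining them, and min/max is the
standard choice. Defuzzification is argmax over condition activations with
ties broken toward the more severe condition (fail-safe clinical prudence);
centroid defuzzification is not meaningful because the output universe is
categorical, not numeric.

The 11 rules cover 11 of the 3·3·3·4·4 = 432 crisp label combinations. The
remainder falls to a fallback that counts abnormal vitals (any label other
than Normal) and maps 0→Healthy, 1→Moderate Unhealthy, 2→Unhealthy,
3→Very Unhealthy, 4→Critical, 5→Very Critical. The fallback is this
package's closure of the rule base, monotone in abnormality by construction;
explicit rules always take precedence, and because rules can fire at
fractional strength in label-overlap zones, the final condition is *not* a
pure function of the crisp labels near boundaries.

The condition codes pin Critical→0 and Unhealthy→3 (fixed by the published
conversion rows that match expert rules); the remaining assignments
(Very Critical→1, Very Unhealthy→2, Moderate Unhealthy→4, Healthy→5) are an
interpretation consistent with all printed constraints. Three published
conversion rows have no matching rule; under the fallback they may receive
different codes than a literal reading of that table would imply. This is
flagged rather than forced: inventing rules to reproduce three table cells
would contradict the abnormal-count closure.

## Triage

The stream processor models the monitoring loop as fixed-size cycles
(default 5 packets — one reading per sensor) because the published
pseudocode gives no timing. Per-sensor normal bands default to each vital's
crisp Normal range (inclusive at both ends). Priority is recomputed from the
current value on every pass (idempotent, no sticky escalation), an
out-of-range packet raises a structured alert-log event (the hardware beep,
as data), and every packet drains every cycle: conservation (output is a
permutation of input), priority dominance and FIFO stability within class
are invariants, all property-tested.

## Beer–Lambert glucose model

Absorbance A = ε·l·c with c in mmol/L (ε per (mmol/L·cm), l in cm), plus
additive Gaussian noise N(0, σ_A). Defaults ε = 1.0, l = 1.0 cm,
σ_A = 0.01: no calibration constants are published for the sensor (only the
940 nm wavelength, which is metadata here), so the defaults are chosen to
give O(1) absorbances at physiologic glucose (A ≈ 5 at 100 mg/dL) and a
sub-mg/dL noise floor. The estimator inverts the noiseless law,
ĝ = A/(ε·l) × 18.016 mg/dL, clamping negative absorbances to zero with a
warning. By the delta method the estimator RMSE is σ_A/(ε·l) × 18.016 mg/dL;
the Monte-Carlo check (n = 1000 draws) must fall within 10 % of that bound.
The glucose unit conversion uses 18.016 mg/dL per mmol/L (molar mass
180.16 g/mol).

## Synthetic cohort

The generator emulates the described study population — 150 diabetic adults,
ages 22–60 uniform, 45 % female, 10 readings per patient at hourly
timestamps — with per-vital truncated normal mixtures chosen to span the
reported measurement ranges:

| vital | components (mean, sd, weight) | truncation |
|---|---|---|
| temperature (°C) | (36.8, 0.7, 0.9), (39.5, 0.5, 0.1) | [30, 42] |
| blood pressure (mmHg) | (100, 15, 0.8), (145, 15, 0.2) | [40, 200] |
| heart rate (bpm) | (120, 25, 1.0) | [50, 220] |
| SpO₂ (%) | (96, 2, 0.85), (88, 4, 0.15) | [60, 100] |
| glucose (mg/dL) | (90, 15, 0.5), (160, 40, 0.5) | [40, 500] |

Only histogram ranges are reported for the original cohort, not
distributions, so these are emulation defaults, not fitted values. Readings
are i.i.d. across time — no circadian glucose dynamics, no within-patient
autocorrelation, no sensor drift — and ground-truth condition labels come
from this package's own inference pipeline. Passing benchmarks therefore
demonstrate internal consistency of the pipeline (a tree can re-learn the
rule table), **not** predictive validity on real patients. Contamination
injects exact-zero/implausible values and blanks into a chosen fraction of
rows, disjointly, and is constructed so that cleaning drops exactly the
contaminated rows.

## ML benchmark

Five classifiers (SVC, Gaussian NB, decision tree, random forest,
Bernoulli NB) with pinned library-default hyperparameters and seeds, a
stratified 80/20 split, and accuracy plus macro-averaged precision/recall/F1
(the averaging scheme is unstated in the source description; macro is the
standard multi-class choice). Features are either raw readings or ordinal
crisp-label encodings (`feature_mode`), since it is unstated which the
original system used. Published accuracy tables for the original private
50/150-patient data are not reproduction targets; the harness reproduces the
protocol, and the shuffled-label control is compared against the
majority-class share (the correct chance ceiling under class imbalance).

## Problem sizes and numerical choices

Default evaluation sizes: 150×10 cohort for label-realism checks, 2,000
records for the closed-loop ML check, 1,000 packets for triage properties,
10,000 random (function, point) pairs for the membership oracle and 1,000
Monte-Carlo draws for the NIR bound — small enough to run in seconds while
leaving the statistical checks well-powered. Membership evaluation is exact
piecewise-linear arithmetic (oracle agreement to 1e-12); ties in argmax
defuzzification are resolved by severity, never by dict order; all RNG is
`numpy.random.default_rng` seeded from the caller.

## Known limitations

- The fallback closure and the code bijection beyond the two pinned codes
  are this package's interpretations; alternative closures are plausible.
- `as_printed` temperature membership is unusable for °C inputs by design
  (kept for fidelity); use the default parameter set for real data.
- Synthetic data carry none of the measurement-error structure of the NIR
  hardware chain (the analog filter stages are out of scope), so benchmark
  numbers say nothing about sensor accuracy.
- Triage models the monitoring loop logically, not temporally: no packet
  loss, no retransmission, no real-time deadlines.
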