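# vitalfuzz

Fuzzy-logic decision support for continuous vital-sign monitoring of diabetic
patients. Wearable sensor platforms for this population stream five vitals —
body temperature (°C), heart rate (bpm), SpO₂ (%), systolic blood pressure
(mmHg) and blood glucose (mg/dL) — and need an interpretable layer that turns
raw readings into an actionable health-condition grade and prioritizes
abnormal telemetry for clinicians. `vitalfuzz` implements that layer at desk
scale for engineers and researchers prototyping such systems: no hardware, no
cloud, just reproducible CSV-in/CSV-out pipelines.

## What it computes

**Fuzzification.** Each vital *x* is mapped to membership degrees
μ_L(x) ∈ [0, 1] over its linguistic labels (e.g. blood pressure ∈
{Low, Normal, Elevated, High}) by trapezoidal/triangular functions
parameterized by breakpoints a ≤ b ≤ c ≤ d: zero outside [a, d], linear rise
on [a, b], plateau 1 on [b, c], linear fall on [c, d].

**Mamdani inference.** A rule base of IF–THEN rules over the five vitals
(AND = min) is evaluated: rule *k*'s firing strength is
w_k = min_i μ_{L_{k,i}}(x_i); per-condition activations are aggregated with
max over rules sharing a consequent; defuzzification picks
argmax with ties broken toward the more severe condition. Conditions are
totally ordered — Healthy < Moderate Unhealthy < Unhealthy < Very Unhealthy <
Critical < Very Critical — and encoded as integer codes
(Critical = 0, Very Critical = 1, Very Unhealthy = 2, Unhealthy = 3,
Moderate Unhealthy = 4, Healthy = 5). When no rule fires, a fallback grades
the condition by the number of vitals whose crisp label is abnormal.

**Triage.** Sensor packets are processed in fixed-size cycles; out-of-range
readings get high priority and an alert, and each cycle transmits
high-priority packets first (FIFO within class). The output is always a
permutation of the input.

**NIR glucose model.** The non-invasive glucose channel follows the
Beer–Lambert law A = ε·l·c (c in mmol/L; 1 mmol/L = 18.016 mg/dL) with
additive Gaussian absorbance noise, plus the exact inverse estimator.

**Synthetic cohort + ML harness.** A seeded generator emulates a diabetic
cohort (150 patients, 22–60 years, 45 % female) with per-vital truncated
normal mixtures, labels each reading through the inference pipeline, and a
harness benchmarks five sklearn classifiers (SVC, Gaussian NB, decision tree,
random forest, Bernoulli NB) on the result.

## Worked example

```python
from vitalfuzz import VitalSample, infer_condition_detailed

# temp 36.5 °C, HR 130 bpm, SpO2 70 %, BP 125 mmHg, glucose 85 mg/dL
sample = VitalSample("patient-1", 0.0, 36.5, 130, 70, 125, 85)
res = infer_condition_detailed(sample)
print(res.condition.label.value, res.condition.code, res.matched_rule)
```

prints

```
Critical 0 printed_rule_1
```

The SpO₂ of 70 % fuzzifies to Critical with degree 1, the other vitals to
Normal/Elevated plateaus, so the expert rule "Normal temp AND normal HR AND
critical SpO₂ AND elevated BP AND normal glucose → Critical" fires at
strength 1.0 and defuzzifies to condition code 0 — the most urgent grade,
which the triage layer would flag and transmit first.

The same pipeline from the shell:

```bash
vitalfuzz simulate --n 150 --readings 10 --seed 42 --out cohort.csv --truth truth.csv
vitalfuzz pipeline --input cohort.csv --conditions conditions.csv --alerts alerts.csv
vitalfuzz mlbench --cohort cohort.csv --truth truth.csv --seed 42 --out metrics.csv
```

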