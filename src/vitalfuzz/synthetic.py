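"""Seeded synthetic diabetic-cohort vital signs and an NIR glucose sensor model.

No patient-level data are deposited with the study this package operationalizes,
so all quantitative evaluation runs on a synthetic cohort that emulates the
described population: 150 adults aged 22-60, 45% female, all diabetic, with
per-vital value distributions spanning the reported measurement ranges.  Each
vital is drawn from a mixture of truncated normals whose components represent
the normal and pathological sub-populations (e.g. a febrile temperature
component, a hyperglycaemic glucose component).  Ground-truth condition labels
are assigned by this package's own inference pipeline, so downstream ML
benchmarks are closed-loop consistency checks, not claims about real patients.

The non-invasive glucose channel follows the Beer-Lambert law
``A = epsilon * l * c``: a 940 nm NIR source shines through the finger and the
absorbance A is linear in the glucose concentration c (here expressed in
mmol/L; epsilon is per (mmol/L * cm), l in cm).  Additive Gaussian noise on A
models photodetector and electronics noise.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import (
    MMOL_TO_MGDL,
    VITAL_ORDER,
    VitalKind,
    VitalSample,
)
from .inference import infer_condition
from .membership import builtin_paramset


@dataclass(frozen=True)
class CohortSpec:
    """Demographics and contamination settings for a synthetic cohort."""

    n_patients: int = 150
    age_range: tuple[int, int] = (22, 60)
    female_fraction: float = 0.45
    readings_per_patient: int = 10
    anomaly_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.readings_per_patient < 1:
            raise ValueError("n_patients and readings_per_patient must be >= 1")
        for name in ("female_fraction", "anomaly_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")


@dataclass(frozen=True)
class MixtureComponent:
    mean: float
    sd: float
    weight: float


@dataclass(frozen=True)
class VitalDistribution:
    """Per-vital mixture of truncated normals."""

    components: dict[VitalKind, tuple[MixtureComponent, ...]]
    truncation: dict[VitalKind, tuple[float, float]]

    def __post_init__(self) -> None:
        for kind, comps in self.components.items():
            total = sum(c.weight for c in comps)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{kind.value}: mixture weights sum to {total}, not 1")

    def mixture_mean(self, kind: VitalKind) -> float:
        """Mean of the truncated mixture (used by Monte-Carlo checks)."""
        lo, hi = self.truncation[kind]
        total = 0.0
        for c in self.components[kind]:
            a, b = (lo - c.mean) / c.sd, (hi - c.mean) / c.sd
            total += c.weight * truncnorm.mean(a, b, loc=c.mean, scale=c.sd)
        return total

    def draw(self, kind: VitalKind, n: int, rng: np.random.Generator) -> np.ndarray:
        comps = self.components[kind]
        lo, hi = self.truncation[kind]
        weights = np.array([c.weight for c in comps])
        which = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for i, c in enumerate(comps):
            mask = which == i
            k = int(mask.sum())
            if k:
                a, b = (lo - c.mean) / c.sd, (hi - c.mean) / c.sd
                out[mask] = truncnorm.rvs(a, b, loc=c.mean, scale=c.sd, size=k, random_state=rng)
        return out


def default_distributions() -> VitalDistribution:
    """Emulation defaults spanning the reported cohort measurement ranges.

    Temperature: mostly afebrile N(36.8, 0.7) with a 10% febrile component
    N(39.5, 0.5).  Blood pressure: normotensive N(100, 15) / hypertensive
    N(145, 15) at 0.8/0.2.  Heart rate: N(120, 25).  SpO2: N(96, 2) with a
    15% hypoxic N(88, 4) component.  Glucose: euglycaemic N(90, 15) and
    hyperglycaemic N(160, 40) at 0.5/0.5, reflecting a diabetic cohort.
    """
    return VitalDistribution(
        components={
            VitalKind.temperature: (
                MixtureComponent(36.8, 0.7, 0.9),
                MixtureComponent(39.5, 0.5, 0.1),
            ),
            VitalKind.blood_pressure: (
                MixtureComponent(100.0, 15.0, 0.8),
                MixtureComponent(145.0, 15.0, 0.2),
            ),
            VitalKind.heart_rate: (MixtureComponent(120.0, 25.0, 1.0),),
            VitalKind.oxygen_saturation: (
                MixtureComponent(96.0, 2.0, 0.85),
                MixtureComponent(88.0, 4.0, 0.15),
            ),
            VitalKind.glucose: (
                MixtureComponent(90.0, 15.0, 0.5),
                MixtureComponent(160.0, 40.0, 0.5),
            ),
        },
        truncation={
            VitalKind.temperature: (30.0, 42.0),
            VitalKind.blood_pressure: (40.0, 200.0),
            VitalKind.heart_rate: (50.0, 220.0),
            VitalKind.oxygen_saturation: (60.0, 100.0),
            VitalKind.glucose: (40.0, 500.0),
        },
    )


def generate_cohort(
    spec: CohortSpec,
    dist: VitalDistribution | None = None,
) -> tuple[list[VitalSample], pd.DataFrame]:
    """Generate a synthetic cohort and its ground-truth table.

    Returns ``(records, truth)``.  ``truth`` holds one row per reading with
    the uncontaminated vitals, patient demographics and the condition label
    and code assigned by the inference pipeline.  ``records`` are the same
    readings after contamination at the spec's anomaly/missing rates (clean
    when both rates are 0).  Fully deterministic under ``spec.seed``.
    """
    if dist is None:
        dist = default_distributions()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients * spec.readings_per_patient

    ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=spec.n_patients)
    female = rng.random(spec.n_patients) < spec.female_fraction

    vitals = {kind: np.round(dist.draw(kind, n, rng), 2) for kind in VITAL_ORDER}

    cfg = builtin_paramset()
    records: list[VitalSample] = []
    rows = []
    idx = 0
    for p in range(spec.n_patients):
        pid = f"P{p + 1:04d}"
        for r in range(spec.readings_per_patient):
            ts = float(r * 3600)  # hourly readings
            sample = VitalSample(
                patient_id=pid,
                timestamp=ts,
                temperature=float(vitals[VitalKind.temperature][idx]),
                heart_rate=float(vitals[VitalKind.heart_rate][idx]),
                oxygen_saturation=float(vitals[VitalKind.oxygen_saturation][idx]),
                blood_pressure=float(vitals[VitalKind.blood_pressure][idx]),
                glucose=float(vitals[VitalKind.glucose][idx]),
            )
            condition = infer_condition(sample, cfg)
            records.append(sample)
            rows.append(
                {
                    "patient_id": pid,
                    "timestamp": ts,
                    "age": int(ages[p]),
                    "sex": "F" if female[p] else "M",
                    **{k.value: sample.value(k) for k in VITAL_ORDER},
                    "condition_label": condition.label.value,
                    "condition_code": condition.code,
                }
            )
            idx += 1
    truth = pd.DataFrame(rows)

    if spec.anomaly_rate > 0 or spec.missing_rate > 0:
        records, _ = inject_anomalies(
            records, spec.anomaly_rate, spec.missing_rate, seed=spec.seed + 1
        )
    return records, truth


#: One guaranteed-implausible replacement value per vital (all are rejected
#: by the default cleaning bounds).
_IMPLAUSIBLE: dict[VitalKind, tuple[float, ...]] = {
    VitalKind.temperature: (3.0, 7.0),
    VitalKind.heart_rate: (500.0,),
    VitalKind.oxygen_saturation: (20.0,),
    VitalKind.blood_pressure: (400.0,),
    VitalKind.glucose: (2000.0,),
}


def inject_anomalies(
    records: list[VitalSample],
    anomaly_rate: float,
    missing_rate: float,
    seed: int = 0,
) -> tuple[list[VitalSample], list[tuple[int, VitalKind, str]]]:
    """Contaminate a fraction of records with impossible or missing readings.

    ``round(anomaly_rate * n)`` records get one vital replaced by zero or an
    implausible value; a disjoint ``round(missing_rate * n)`` records get one
    vital blanked (NaN).  Returns the contaminated records and an index of
    ``(row, vital, reason)`` entries.  Cleaning drops exactly the
    contaminated records.
    """
    for name, rate in (("anomaly_rate", anomaly_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    n = len(records)
    rng = np.random.default_rng(seed)
    n_anom = round(anomaly_rate * n)
    n_miss = min(round(missing_rate * n), n - n_anom)
    chosen = rng.choice(n, size=n_anom + n_miss, replace=False) if n_anom + n_miss else np.array([], dtype=int)
    out = list(records)
    index: list[tuple[int, VitalKind, str]] = []
    for j, row in enumerate(chosen):
        row = int(row)
        kind = VITAL_ORDER[int(rng.integers(len(VITAL_ORDER)))]
        if j < n_anom:
            pool = (0.0,) + _IMPLAUSIBLE[kind]
            value = float(pool[int(rng.integers(len(pool)))])
            reason = "impossible_value" if value == 0.0 else "out_of_physical_bounds"
        else:
            value = float("nan")
            reason = "missing"
        out[row] = replace(out[row], **{kind.value: value})
        index.append((row, kind, reason))
    return out, index


def records_to_frame(records: list[VitalSample]) -> pd.DataFrame:
    """Tabulate records with the canonical CSV column order."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "timestamp": r.timestamp,
                **{k.value: r.value(k) for k in VITAL_ORDER},
            }
            for r in records
        ],
        columns=["patient_id", "timestamp", *[k.value for k in VITAL_ORDER]],
    )


def frame_to_records(frame: pd.DataFrame) -> list[VitalSample]:
    """Parse the canonical CSV schema back into samples (blanks become NaN)."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            VitalSample(
                patient_id=str(row.patient_id),
                timestamp=float(row.timestamp),
                temperature=float(row.temperature),
                heart_rate=float(row.heart_rate),
                oxygen_saturation=float(row.oxygen_saturation),
                blood_pressure=float(row.blood_pressure),
                glucose=float(row.glucose),
            )
        )
    return records


@dataclass(frozen=True)
class NIRModel:
    """Beer-Lambert absorbance model for the 940 nm NIR glucose channel.

    ``epsilon`` is the effective molar absorptivity per (mmol/L * cm),
    ``path_length`` the optical path through the finger in cm and
    ``noise_sd`` the additive Gaussian absorbance noise.  The wavelength is
    metadata; it does not enter the law.
    """

    epsilon: float = 1.0
    path_length: float = 1.0
    noise_sd: float = 0.01
    seed: int = 0
    wavelength_nm: float = 940.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.path_length <= 0:
            raise ValueError("epsilon and path_length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_absorbance(
    glucose_mgdl: float | np.ndarray,
    model: NIRModel,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Absorbance of the NIR channel at a given glucose level.

    ``A = epsilon * l * c`` with c in mmol/L, plus N(0, noise_sd) noise drawn
    from ``rng`` (or a generator seeded by ``model.seed``).
    """
    g = np.asarray(glucose_mgdl, dtype=float)
    if np.any(g < 0):
        raise ValueError("glucose must be >= 0")
    c_mmol = g / MMOL_TO_MGDL
    a = model.epsilon * model.path_length * c_mmol
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        a = a + rng.normal(0.0, model.noise_sd, size=a.shape)
    return float(a) if np.isscalar(glucose_mgdl) else a


def estimate_glucose_from_absorbance(
    absorbance: float | np.ndarray, model: NIRModel
) -> float | np.ndarray:
    """Invert the noiseless Beer-Lambert law to mg/dL.

    Negative absorbances (possible under noise at low glucose) are clamped
    to 0 with a warning.
    """
    a = np.asarray(absorbance, dtype=float)
    if np.any(a < 0):
        warnings.warn("negative absorbance clamped to 0", stacklevel=2)
        a = np.clip(a, 0.0, None)
    c_mmol = a / (model.epsilon * model.path_length)
    g = c_mmol * MMOL_TO_MGDL
    return float(g) if np.isscalar(absorbance) else g
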