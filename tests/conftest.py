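import pytest

from vitalfuzz import (
    VITAL_ORDER,
    VitalKind,
    VitalSample,
    build_rulebase,
    builtin_paramset,
    default_range_table,
)

# One representative value per (vital, label) lying on that label's
# membership plateau, inside its crisp range, and inside the cleaning
# plausibility bounds, so the same samples are usable end to end.
PLATEAU = {
    VitalKind.temperature: {"Low": 30.0, "Normal": 36.5, "High": 40.0},
    VitalKind.heart_rate: {"Low": 60.0, "Normal": 130.0, "High": 170.0},
    VitalKind.oxygen_saturation: {"Critical": 70.0, "Worrisome": 91.5, "Normal": 97.0},
    VitalKind.blood_pressure: {"Low": 60.0, "Normal": 105.0, "Elevated": 124.5, "High": 150.0},
    VitalKind.glucose: {"Low": 40.0, "Normal": 85.0, "Elevated": 110.0, "High": 160.0},
}


def sample_from_labels(temp, hr, spo2, bp, gl, patient_id="p", timestamp=0.0) -> VitalSample:
    """Build a sample whose vitals sit on the plateaus of the given labels."""
    return VitalSample(
        patient_id=patient_id,
        timestamp=timestamp,
        temperature=PLATEAU[VitalKind.temperature][temp],
        heart_rate=PLATEAU[VitalKind.heart_rate][hr],
        oxygen_saturation=PLATEAU[VitalKind.oxygen_saturation][spo2],
        blood_pressure=PLATEAU[VitalKind.blood_pressure][bp],
        glucose=PLATEAU[VitalKind.glucose][gl],
    )


@pytest.fixture(scope="session")
def range_table():
    return default_range_table()


@pytest.fixture(scope="session")
def cfg_default():
    return builtin_paramset("range_consistent")


@pytest.fixture(scope="session")
def cfg_printed():
    return builtin_paramset("as_printed")


@pytest.fixture(scope="session")
def rulebase():
    return build_rulebase()
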