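import pytest
from hypothesis import settings

from contrastflow import IOPROMIDE_300, Patient, Sex, default_calibration

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibration():
    """(k, FlowCalibration) from the built-in reference anchor at 300 mgI/mL."""
    return default_calibration(IOPROMIDE_300.iodine_concentration)


@pytest.fixture(scope="session")
def agent():
    return IOPROMIDE_300


@pytest.fixture
def reference_patient():
    """The calibration anchor's patient: male, 1.80 m, 80 kg."""
    return Patient(sex=Sex.MALE, height=1.80, weight=80.0, heart_rate=64.0)
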