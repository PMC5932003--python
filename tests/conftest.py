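import numpy as np
import pytest

from peatflux.calibrate import RadiocarbonDate
from peatflux.curves import CalibrationCurve, synthetic_calibration_curve


@pytest.fixture(scope="session")
def identity_curve():
    """Linear curve mu(theta) = theta with negligible curve error."""
    return CalibrationCurve(
        cal_age=np.array([0.0, 20000.0]),
        c14_age=np.array([0.0, 20000.0]),
        curve_sigma=np.array([1e-6, 1e-6]),
        name="identity",
    )


@pytest.fixture(scope="session")
def standin_curve():
    """Holocene part of the synthetic stand-in curve (fast to calibrate on)."""
    return synthetic_calibration_curve(cal_max=15_000.0)


@pytest.fixture(scope="session")
def full_standin_curve():
    return synthetic_calibration_curve()


@pytest.fixture()
def linear_dates():
    """Five dates lying exactly on age = 10 x depth."""
    return [
        RadiocarbonDate(d, f"L{d}", 10.0 * d, 1.0) for d in (10, 30, 50, 70, 90)
    ]
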