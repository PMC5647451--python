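import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caripix.calibration import CalibrationCurve
from caripix.synthetic import BeamConfig, SpecimenTruth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def beam() -> BeamConfig:
    return BeamConfig()


@pytest.fixture
def truth() -> SpecimenTruth:
    return SpecimenTruth()


def true_curves(beam: BeamConfig) -> dict[str, CalibrationCurve]:
    """Exact calibration curves matching the generator's counting model:
    slope = yield, intercept = background (counts per unit charge)."""
    return {
        "pixe_ca": CalibrationCurve(
            kind="pixe_ca", slope=beam.yield_ca, intercept=beam.background_ca,
            r_squared=1.0, unit="wt%",
        ),
        "pige_f": CalibrationCurve(
            kind="pige_f", slope=beam.yield_f, intercept=beam.background_f,
            r_squared=1.0, unit="ppm",
        ),
    }
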