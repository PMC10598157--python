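import numpy as np
import pytest

from ctbsp.calibration import fit_bilinear_calibration, RodMeasurement
from ctbsp.phantom import default_calibration, generate_phantom, pig_like_phantom


@pytest.fixture(scope="session")
def calibration():
    """Bilinear calibration fitted to the bundled synthetic rod table."""
    return default_calibration()


@pytest.fixture(scope="session")
def exact_calibration():
    """Calibration whose rods lie exactly on two lines (no fit residual)."""
    rods = [
        RodMeasurement("air", -1000.0, 0.0),
        RodMeasurement("water", 0.0, 1000.0),
        RodMeasurement("muscle", 100.0, 1100.0),
        RodMeasurement("trabecular", 1000.0, 1820.0),
        RodMeasurement("cortical", 2000.0, 2620.0),
    ]
    return fit_bilinear_calibration(rods)


@pytest.fixture(scope="session")
def coarse_pig(calibration):
    """Noise-free pig-like phantom voxelized at 2 mm (fast end-to-end runs)."""
    spec = pig_like_phantom(spacing=2.0)
    volume, landmarks = generate_phantom(spec, calibration)
    return spec, volume, landmarks


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
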