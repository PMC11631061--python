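import numpy as np
import pytest
from hypothesis import settings

from atriapace.calibration import BaselineCalibration, calibrated_phenotype
from atriapace.sweep import PacingSweep

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration_result():
    """Baseline HFpEF calibration, fitted once per session."""
    return BaselineCalibration().fit()


@pytest.fixture(scope="session")
def hfpef_sweeps():
    """Full 9x31 rate x PR grids for the calibrated phenotype with normal
    (fraction 1.0) and myopathic (0.5) atria."""
    normal = PacingSweep(calibrated_phenotype(1.0)).run()
    myo = PacingSweep(calibrated_phenotype(0.5)).run()
    return {"normal": normal, "myopathy": myo}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240718)
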