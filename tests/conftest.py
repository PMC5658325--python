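import numpy as np
import pytest
from hypothesis import settings

from lfaquant import calibration as cal
from lfaquant import signal_extraction as se
from lfaquant import strip_model as sm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def geometry() -> sm.StripGeometry:
    return sm.StripGeometry()


@pytest.fixture
def noiseless_strip(geometry):
    """Factory: render a noise-free strip at a given true T/C."""

    def _render(tc_true: float, **optics_kw) -> se.StripImage:
        return sm.render_strip(
            geometry, sm.OpticalModel(tc_ratio_true=tc_true, noise_sigma=0.0, **optics_kw)
        )

    return _render


@pytest.fixture
def serum_4pl() -> cal.FourPLCalibration:
    return cal.SERUM_CALIBRATOR_4PL


@pytest.fixture
def brute_force_auc():
    """Exhaustive pair-counting Mann-Whitney oracle (ties count half)."""

    def _auc(scores, labels):
        scores = np.asarray(scores, float)
        labels = np.asarray(labels, bool)
        pos, neg = scores[labels], scores[~labels]
        total = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        return total / (len(pos) * len(neg))

    return _auc
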