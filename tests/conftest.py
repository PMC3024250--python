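import numpy as np
import pytest

from epifract.imaging import GrayImage, ImageCalibration


@pytest.fixture
def unit_calibration():
    return ImageCalibration(1.0)


@pytest.fixture
def default_calibration():
    return ImageCalibration()


@pytest.fixture
def gray(unit_calibration):
    """Factory wrapping a raw array as a GrayImage with unit calibration."""

    def _make(pixels, rng=None, calibration=None):
        pixels = np.asarray(pixels, dtype=np.float64)
        if rng is None:
            rng = (0.0, max(255.0, float(pixels.max(initial=0.0))))
        return GrayImage(pixels, calibration or unit_calibration, rng)

    return _make
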