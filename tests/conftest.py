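import numpy as np
import pytest

from bladekit import phantom
from bladekit.dce import AIF, ConversionSettings

# cohort-mean ground truth used across the recovery tests
NGIVIM_TRUTH = {"S0": 1000.0, "f": 0.24, "Dstar": 25.57e-3, "D": 1.21e-3, "K": 0.41}
ADC_TRUTH = 1.22e-3
T10_TRUTH = 1.16
EXT_TOFTS_TRUTH = {"Ktrans": 0.27, "ve": 0.38, "vp": 0.03}
PATLAK_TRUTH = {"Ktrans": 0.076, "vp": 0.079}


@pytest.fixture
def bvalues():
    return phantom.DEFAULT_BVALUES


@pytest.fixture
def t_min():
    return phantom.DEFAULT_FRAME_TIMES_S / 60.0


@pytest.fixture
def aif(t_min):
    return phantom.population_aif(t_min)


@pytest.fixture
def const_aif(t_min):
    return AIF(t_min=t_min, Cp_mM=np.ones_like(t_min))


@pytest.fixture
def settings():
    return ConversionSettings()
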