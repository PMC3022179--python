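import numpy as np
import pytest

from singlechan import GatingModel, IonConditions

# Study conditions at 60 mV: central conductance (nS) and opening rate
# (events/min) without and with choline 5e-11 M
CONTROL_RATE = 7.73
CHOLINE_RATE = 15.97
CONTROL_LAMBDA = 0.161
CHOLINE_LAMBDA = 0.215

# Open-lifetime parameters at 60 mV: control single exponential vs the
# choline-cis two-component mixture
TAU_SINGLE_60MV = 2.07
TAU1_CHOLINE_CIS = 1.53
TAU2_CHOLINE_CIS = 8.34
MIX_W_FAST = 0.8


@pytest.fixture
def control_model():
    return GatingModel(
        opening_rate=CONTROL_RATE,
        dwell_mixture=(1.0, TAU_SINGLE_60MV, None),
        unit_conductance=(CONTROL_LAMBDA, 0.02),
        noise_sd=1.0,
    )


@pytest.fixture
def kcl_gradient():
    """100 mM cis / 50 mM trans KCl at the 23 degC bath temperature."""
    return IonConditions.kcl(100.0, 50.0, 23.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
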