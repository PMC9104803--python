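import numpy as np
import pytest

from fesloop.pid import PIDGains
from fesloop.plant import default_plant
from fesloop.session import default_config
from fesloop.waveform import StimulationParameters


@pytest.fixture
def sagittal_gains() -> PIDGains:
    """Published PI gains for the dorsiflexion/plantar-flexion controller."""
    return PIDGains(kp=8.2, ki=3.8, kd=0.0, u_min=-14.0, u_max=10.0)


@pytest.fixture
def frontal_gains() -> PIDGains:
    """Published PI gains for the inversion/eversion controller."""
    return PIDGains(kp=8.1, ki=3.2, kd=0.0, u_min=-12.0, u_max=14.0)


@pytest.fixture
def reference_plant():
    return default_plant()


@pytest.fixture
def reference_config():
    return default_config(seed=1)


@pytest.fixture
def stim_50hz_200us() -> StimulationParameters:
    return StimulationParameters(
        channel_id=0, frequency_hz=50.0, pulse_duration_us=200.0, amplitude_duty_pct=5.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
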