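import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hvgating import (
    ConductanceSpec,
    RecordingConditions,
    VoltageStepProtocol,
)


@pytest.fixture
def symmetric_ph():
    return RecordingConditions(ph_i=6.5, ph_o=6.5)


@pytest.fixture
def aq_spec():
    """Depolarization-activated conductance with the published tail-fit gating."""
    return ConductanceSpec(
        label="AQ",
        g_max=22.2,
        v_half=26.3,
        slope_dx=16.3,
        polarity="depolarization",
        tau_act=20.0,
        tau_deact=10.0,
    )


@pytest.fixture
def leak_spec():
    return ConductanceSpec(label="LEAK", g_max=1.5, is_ohmic=True)


@pytest.fixture
def short_protocol():
    return VoltageStepProtocol(
        v_hold=-60.0,
        step_voltages=tuple(np.arange(-100.0, 101.0, 20.0)),
        step_duration=120.0,
        v_tail=-90.0,
        tail_duration=80.0,
        sample_interval=0.5,
        pre_step_baseline=10.0,
    )
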