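import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import heatpulse as hp

K_DEFAULT = 2.5e-3  # cm^2/s
X_DEFAULT = 0.5  # cm


@pytest.fixture
def geometry():
    return hp.ProbeGeometry(x_d=X_DEFAULT, x_u=X_DEFAULT, depths=(0.5, 1.5, 2.5))


@pytest.fixture
def single_depth_geometry():
    return hp.ProbeGeometry(x_d=X_DEFAULT, x_u=X_DEFAULT, depths=(0.5,))


def make_medium(v_h=0.0, t0=0.0, k=K_DEFAULT, q_amp=3.2):
    return hp.MediumParams(k=k, v_h=v_h, q_amp=q_amp, t0=t0)


@pytest.fixture
def medium_factory():
    return make_medium


@pytest.fixture
def noiseless():
    return hp.NOISELESS
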