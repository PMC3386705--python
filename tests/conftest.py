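import numpy as np
import pytest

from flimkit import AcquisitionConfig, DecayModel
from flimkit.estimators import build_omega_lut


@pytest.fixture(scope="session")
def omega_lut():
    return build_omega_lut()


@pytest.fixture
def single_exp():
    """Canonical single-exponential model: A = 1000/ns, tau = 1 ns."""
    return DecayModel(amplitudes=[1000.0], lifetimes=[1.0])


@pytest.fixture
def biexp_model():
    """Equal-amplitude bi-exponential with tau 2 ns / 4 ns."""
    return DecayModel(amplitudes=[1000.0, 1000.0], lifetimes=[2.0, 4.0])


def gated_cfg(h: float, S: float, R: float, scheme: str = "correlated-gates"):
    """Gate geometry with gate-1 width h; the gate window is [0, R*h)."""
    return AcquisitionConfig(T=h, M=1, S=S, R=R, scheme=scheme)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
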