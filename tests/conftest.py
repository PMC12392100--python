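import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def step_input():
    from consolidyn import make_input_signal

    return make_input_signal("step", amplitude=1.0, onset=0.0)


@pytest.fixture
def unit_input():
    from consolidyn import make_input_signal

    return make_input_signal("constant", amplitude=1.0)


@pytest.fixture
def stable_toy_params():
    from consolidyn import ToyParams

    return ToyParams(w_star=1.0, eta1=0.1, eta2=0.05, mu=0.0)


@pytest.fixture
def small_integrator():
    """A 5-neuron detuned integrator in the stable learning regime."""
    from consolidyn import build_system

    return build_system(N=5, c_align_target=0.8, lambda0=1.05, seed=3, eta1=5e-3, eta2=5e-4)


def rms(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(a))))
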