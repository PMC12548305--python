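import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import optofear as of

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    """One acute-experiment trial: 20 Hz trains of 0.5/1/5/15 s, 430 pulses."""
    return of.gen_protocol(seed=1)


@pytest.fixture(scope="session")
def tiny_protocol():
    """Single 1-s train at 20 Hz after a short baseline (20 pulses)."""
    return of.gen_protocol(
        train_spec=[(1.0, "11mW")], baseline_s=10.0, inter_train_gap=5.0, seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def poisson_train(rate, duration, seed, unit_id="u0"):
    return of.gen_background_train(rate, duration, isi_shape=1.0, seed=seed, unit_id=unit_id)
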