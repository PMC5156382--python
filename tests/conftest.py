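import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import climwindow as cw

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def signal_dataset():
    """A moderate-signal synthetic dataset shared by read-only tests."""
    spec = cw.SyntheticSpec(n_records=30, true_window=(20, 10), beta=-3.0,
                            target_r2=0.5, seed=99)
    series, biol = cw.gen_dataset(spec)
    return spec, series, biol


@pytest.fixture()
def baseline_of():
    def make(biol, family="gaussian", formula=None):
        return cw.BaselineSpec(formula or f"{biol.response_name} ~ 1",
                               biol.to_frame(), family=family)
    return make
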