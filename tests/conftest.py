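import math

import pytest
from hypothesis import HealthCheck, settings

from microbcr.synthetic import DiauxicModelParams, SyntheticConfig, make_cultivation_record

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

LN20 = math.log(20.0)


@pytest.fixture()
def noiseless_cfg():
    return SyntheticConfig(seed=7, noise_sd=0.0)


@pytest.fixture(scope="session")
def diauxic_record():
    """Noiseless reference cultivation at the default (published-timeline)
    parameters, 1-min sampling."""
    return make_cultivation_record(
        DiauxicModelParams(), SyntheticConfig(seed=11), duration_h=12.0,
        sampling_dt_h=1.0 / 60.0,
    )
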