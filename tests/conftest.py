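import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucleoshuttle.synthetic import SyntheticSpec, generate_field

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: compact geometry for fast unit tests; intensity/noise parameters keep
#: their defaults so behaviour matches full-size fields
SMALL_GEOMETRY = dict(
    image_height_px=300,
    image_width_px=300,
    n_nuclei=4,
    nucleus_radius_range_px=(22.0, 32.0),
    nucleoli_per_nucleus_range=(2, 4),
    nucleolus_radius_range_px=(4.0, 8.0),
)


def small_spec(**overrides) -> SyntheticSpec:
    kwargs = dict(SMALL_GEOMETRY)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def noiseless_spec(**overrides) -> SyntheticSpec:
    return small_spec(photon_scale=0.0, read_noise_sigma=0.0, **overrides)


@pytest.fixture
def noisy_field():
    return generate_field(small_spec(seed=11))


@pytest.fixture
def noiseless_field():
    return generate_field(noiseless_spec(seed=11))
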