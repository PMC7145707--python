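import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smfret_unwind import ConditionSpec, KineticParams, PhotophysicsParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def clean_photophysics() -> PhotophysicsParams:
    """Noise-free, no donor-only molecules: E is exactly the state value."""
    return PhotophysicsParams(
        noise_sd=0.0, background=0.0, donor_only_fraction=0.0, total_intensity=400.0
    )


@pytest.fixture
def tight_photophysics() -> PhotophysicsParams:
    """Well-separated E peaks (per-frame E SD ~0.02), no donor-only molecules."""
    return PhotophysicsParams.with_fret_sd(0.02, e_state=0.75, donor_only_fraction=0.0)


def make_condition(p_unwound: float, photophysics: PhotophysicsParams, **kwargs) -> ConditionSpec:
    defaults = dict(label="test", n_pd=0)
    defaults.update(kwargs)
    return ConditionSpec(
        kinetics=KineticParams(p_unwound=p_unwound), photophysics=photophysics, **defaults
    )


@pytest.fixture
def condition_factory():
    return make_condition
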