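import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from relkin import ReleaseCurve, SyntheticSpec, paper_like_scenarios, simulate_release


@pytest.fixture(scope="session")
def scenarios() -> dict:
    """Named paper-like scenarios, keyed by formulation name."""
    return {s.name: s for s in paper_like_scenarios()}


@pytest.fixture(scope="session")
def composite_scenario(scenarios) -> SyntheticSpec:
    return scenarios["mPEG-PCL-Fe-BTC-PTX"]


def noiseless_curve(spec: SyntheticSpec) -> ReleaseCurve:
    """Exact forward-model curve for a scenario (helper, not a fixture)."""
    return simulate_release(dataclasses.replace(spec, noise_sd=0.0))
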