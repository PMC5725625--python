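import pytest
from hypothesis import HealthCheck, settings

import cyclecal as cc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A derived-cycle set from a small synthetic cohort (shared, read-only)."""
    cfg = cc.cohort_preset(n_women=400, seed=5)
    return cc.derive_cycles(cc.generate_population(cfg))


@pytest.fixture(scope="session")
def eval_cohort():
    """A mid-sized cohort for evaluation-stage statistics."""
    cfg = cc.cohort_preset(n_women=3000, seed=17)
    return cc.derive_cycles(cc.generate_population(cfg))
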