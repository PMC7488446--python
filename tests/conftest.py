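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
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort_spec():
    """An 18-subject two-study cohort small enough for fast end-to-end runs."""
    from t2het.synthetic import CohortSpec

    return CohortSpec(
        group_sizes=(8, 6, 4),
        study_counts={"HC": (4, 4), "MCI": (3, 3), "AD": (2, 2)},
        seed=11,
    )


@pytest.fixture
def small_phantom():
    from t2het.synthetic import make_phantom

    return make_phantom(noise_model="none", noise_sd=0.0)
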