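import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def small_cohort_config():
    from vacuoquant.synth import CohortConfig

    return CohortConfig(
        n_patients_per_class={"control": 4, "protracted": 3, "classical": 4},
        samples_per_patient=(2, 3),
        seed=42,
    )
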