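import numpy as np
import pandas as pd
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
    return np.random.default_rng(20250921)


@pytest.fixture
def small_cohort():
    """Six subjects of both sexes with a hand-set criterion BSA."""
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(6)],
            "sex": ["male", "male", "male", "female", "female", "female"],
            "weight_kg": [77.0, 68.5, 82.0, 58.0, 62.5, 55.0],
            "height_cm": [185.0, 176.0, 189.0, 165.0, 170.0, 160.0],
            "criterion_bsa_m2": [1.93, 1.78, 2.02, 1.58, 1.68, 1.52],
        }
    )


@pytest.fixture
def echo_cohort(small_cohort):
    """The small cohort with plausible echo measurements attached."""
    cohort = small_cohort.copy()
    cohort["lvedd_mm"] = [52.0, 50.0, 56.0, 47.0, 49.0, 46.0]
    cohort["lvedv_ml"] = [147.0, 121.0, 155.0, 95.0, 104.0, 90.0]
    cohort["rvbd_mm"] = [39.0, 34.0, 44.0, 31.0, 33.0, 30.0]
    return cohort
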