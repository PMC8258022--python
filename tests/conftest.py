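import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_table():
    """Analysis-ready table-mode cohort, shared across tests."""
    from upfmed.cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n=1500, seed=424)).table


@pytest.fixture(scope="session")
def catalogue():
    from upfmed.cohort import build_catalogue

    codes, frame = build_catalogue()
    return codes, frame


def make_null_mediation_frame(rng: np.random.Generator, n: int = 2000, a: float = 0.5):
    """Exposure-mediator-outcome frame with no mediated effect (b = 0)."""
    x = rng.standard_normal(n)
    m = a * x + rng.standard_normal(n)
    y = rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})
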