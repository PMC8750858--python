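import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import autoahp as aa

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-row synthetic cohort shared across tests (seed 11)."""
    df, truth = aa.generate_cohort(aa.GeneratorParams(n=2000, seed=11))
    return df, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def cyclic3():
    """The classic maximally-inconsistent 3x3 matrix (CR ~ 1.15)."""
    return aa.PairwiseMatrix([[1, 3, 1 / 3], [1 / 3, 1, 3], [3, 1 / 3, 1]])
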