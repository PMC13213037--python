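import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ivffmcdm as m

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def comparison_scale():
    return m.builtin_scale("comparison")


@pytest.fixture(scope="session")
def rating_scale():
    return m.builtin_scale("rating")


@pytest.fixture(scope="session")
def forward_series():
    return m.load_fixture("piprecia_forward")


@pytest.fixture(scope="session")
def inverse_series():
    return m.load_fixture("piprecia_inverse")


@pytest.fixture(scope="session")
def rating_panel():
    return m.load_fixture("rating_panel")


@pytest.fixture(scope="session")
def score_matrix():
    return m.load_fixture("score_matrix")


@pytest.fixture(scope="session")
def published_Q():
    return m.load_fixture("mairca_Q")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_valid_ivofn(rng: np.random.Generator, q: int = 3) -> m.IVOFN:
    """Uniform-ish draw from the valid IVOFN region for rung q."""
    mu_high = rng.uniform(0.0, 1.0)
    nu_cap = (1.0 - mu_high**q) ** (1.0 / q)
    nu_high = rng.uniform(0.0, nu_cap)
    mu_low = rng.uniform(0.0, mu_high)
    nu_low = rng.uniform(0.0, nu_high)
    return m.IVOFN(mu_low, mu_high, nu_low, nu_high, q)
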