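import numpy as np
import pytest

from imbayes import Condition


@pytest.fixture
def short_cond() -> Condition:
    """A short-display condition with moderate external uncertainty."""
    return Condition(display_regime="short", mu_target=5.0, sigma_external=3.0)


@pytest.fixture
def short_cond_no_ext() -> Condition:
    return Condition(display_regime="short", mu_target=8.0, sigma_external=0.0)


@pytest.fixture
def unlimited_cond() -> Condition:
    """Unlimited display, no sensory noise: the closed-form likelihood path."""
    return Condition(
        display_regime="unlimited",
        mu_target=5.0,
        sigma_external=3.0,
        fixed_sensory_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
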