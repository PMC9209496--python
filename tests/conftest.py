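import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import protrep as P

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_corpus():
    """3 families x 12 members — cheap end-to-end fixture."""
    return P.generate_corpus(P.FamilySpec(n_families=3, members_per_family=12, seed=7))


@pytest.fixture(scope="session")
def default_corpus():
    """The 5 x 40 benchmark corpus used by the recovery analyses."""
    return P.generate_corpus(P.FamilySpec(seed=11))


@pytest.fixture(scope="session")
def tiny_lm_config():
    return P.LanguageModelConfig(num_layers=2, hidden_units=16, batch_size=8,
                                 warmup_steps=10, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
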