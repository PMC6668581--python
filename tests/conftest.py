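import pytest
from hypothesis import HealthCheck, settings

from btspred import FixtureSpec, generate_fixture
from btspred.pipeline import train_models

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cvelia_fixture():
    """200 proteins per class, Chromera-like Phe(+1) conservation."""
    return generate_fixture(FixtureSpec(n_per_class=200, seed=7,
                                        species_profile="cvelia_like"))


@pytest.fixture(scope="session")
def cvelia_models(cvelia_fixture):
    _, entries = cvelia_fixture
    return train_models(entries, species_tag="cvelia_like")


@pytest.fixture(scope="session")
def heldout_fixture():
    """Held-out mixed set from an independent seed."""
    return generate_fixture(FixtureSpec(n_per_class=100, seed=8,
                                        species_profile="cvelia_like"))
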