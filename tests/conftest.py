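import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def volatile_reference():
    from tomatoflavor import load_volatile_reference

    return load_volatile_reference()


@pytest.fixture(scope="session")
def taste_table():
    from tomatoflavor import load_taste_table

    return load_taste_table()


@pytest.fixture(scope="session")
def refs():
    from tomatoflavor import compound_refs

    return compound_refs()


@pytest.fixture(scope="session")
def small_panel():
    """A compact noiseless synthetic panel shared across tests."""
    from tomatoflavor.synthetic import SimulationConfig, generate_panel

    return generate_panel(
        SimulationConfig(seed=11, n_accessions=12, n_volatiles=10, area_noise_cv=0.0)
    )
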