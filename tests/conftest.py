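import pytest
from hypothesis import settings

from anchorinv.synthetic import PopulationSpec, VignetteDesign, simulate_survey

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_spec():
    return PopulationSpec.default()


@pytest.fixture(scope="session")
def default_design():
    return VignetteDesign.default()


@pytest.fixture(scope="session")
def survey(default_spec, default_design):
    """One default-size synthetic survey (two groups, 145/91)."""
    return simulate_survey(default_spec, default_design, (145, 91), seed=0)


@pytest.fixture(scope="session")
def big_survey(default_spec, default_design):
    """Larger survey for frequency-level checks."""
    return simulate_survey(default_spec, default_design, (1000, 1000), seed=1)
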