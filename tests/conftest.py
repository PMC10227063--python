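import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caxport.restraint_model import build_default_restraints, sample_ensemble
from caxport.synthetic_data import build_scaffold, plant_survey_fixtures

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scaffold():
    return build_scaffold()


@pytest.fixture(scope="session")
def restraints(scaffold):
    return build_default_restraints(scaffold)


@pytest.fixture(scope="session")
def small_ensemble(scaffold, restraints):
    """A dozen restraint-satisfying models, shared across test modules."""
    return sample_ensemble(scaffold, restraints, n_models=12, seed=3)


@pytest.fixture(scope="session")
def survey_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("survey_fixtures")
    paths, truth = plant_survey_fixtures(out, seed=11)
    return out, paths, truth
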