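import pytest

from mscea.config import load_config
from mscea.sensitivity import psa_config_from, run_psa
from mscea.synthetic_cohort import CohortSpec, generate_cohort
from mscea.valuesets import synthetic_reference


@pytest.fixture(scope="session")
def base_cfg():
    return load_config()


@pytest.fixture(scope="session")
def value_set():
    return synthetic_reference()


@pytest.fixture(scope="session")
def cohort(base_cfg):
    """The study-sized synthetic sample: 60 patients per arm, seed 1."""
    return generate_cohort(CohortSpec.from_config(base_cfg, seed=1))


@pytest.fixture(scope="session")
def psa_samples(base_cfg):
    """Full 5000-iteration probabilistic sensitivity analysis, seed 1."""
    return run_psa(base_cfg, psa_config_from(base_cfg, seed=1, n_iterations=5000))
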