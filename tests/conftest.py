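import warnings

import pytest
from hypothesis import settings

import infoval as iv

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_configs():
    return iv.build_default_configurations()


@pytest.fixture(scope="session")
def group_defaults():
    return iv.GroupParameters.defaults()


@pytest.fixture(scope="session")
def small_cohort(group_defaults):
    """Six synthetic subjects and their choices under the winning model."""
    subjects = iv.sample_subjects(group_defaults, 6, seed=11)
    data = iv.simulate_dataset(iv.winning_model(), subjects, seed=12)
    return subjects, data


@pytest.fixture(scope="session")
def fast_config():
    return iv.SamplerConfig(chains=2, warmup=300, draws=300, seed=5)


@pytest.fixture(scope="session")
def small_fit(small_cohort, fast_config):
    """One reusable hierarchical fit of the winning model on the small cohort."""
    _, data = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return iv.fit_hierarchical(iv.winning_model(), data, fast_config)
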