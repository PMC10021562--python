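import numpy as np
import pytest

import tourpref as tp


@pytest.fixture(scope="session")
def attributes():
    return tp.default_attributes()


@pytest.fixture(scope="session")
def design(attributes):
    """The eight-task D-efficient instrument used across estimation tests."""
    return tp.default_design(seed=1, n_restarts=2)


@pytest.fixture(scope="session")
def generator(design):
    return tp.default_generator_config(seed=3, design=design)


@pytest.fixture(scope="session")
def dataset(generator):
    """One simulated study: 242 respondents x 8 tasks x 3 alternatives."""
    return tp.generate_choices(generator)


@pytest.fixture(scope="session")
def mnl_result(dataset):
    return tp.fit_mnl(dataset)


@pytest.fixture(scope="session")
def small_dataset(design):
    """Reduced-scale panel (80 respondents) for the slower mixed-logit paths."""
    gen = tp.default_generator_config(seed=7, design=design, n_respondents=80)
    return tp.generate_choices(gen)


@pytest.fixture(scope="session")
def toy_binary_attribute():
    return tp.AttributeSpec(name="flag", levels=("on", "off"), codes=("flag_on", "flag_off"))


@pytest.fixture(scope="session")
def survey(design):
    gen = tp.default_generator_config(seed=5, design=design)
    return tp.generate_survey(gen)
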