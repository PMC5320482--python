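import numpy as np
import pytest

from quechemo import pipeline, synthetic
from quechemo.designs import Factor, generate_ccd, generate_plackett_burman


@pytest.fixture(scope="session")
def screening_factors():
    return pipeline.SCREENING_FACTORS


@pytest.fixture(scope="session")
def optimization_factors():
    return pipeline.OPTIMIZATION_FACTORS


@pytest.fixture()
def pb_design(screening_factors):
    return generate_plackett_burman(screening_factors, n_center=3)


@pytest.fixture()
def ccd_design(optimization_factors):
    return generate_ccd(optimization_factors, n_center=6)


@pytest.fixture()
def truth():
    return synthetic.make_default_truth(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
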