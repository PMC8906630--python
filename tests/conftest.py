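import numpy as np
import pytest

from dermachroma import pipeline
from dermachroma.synthetic import ErythemaModelParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three-patient cohort with small fast images."""
    params = ErythemaModelParams(image_size=(32, 32))
    return generate_cohort(n_patients=3, params=params, seed=11)


@pytest.fixture(scope="session")
def tiny_records(tiny_cohort):
    return pipeline.extract_all(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
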