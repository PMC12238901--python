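import numpy as np
import pandas as pd
import pytest

from d3cr.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=451) with its ground truth."""
    return generate_cohort(CohortParams(n=451, seed=7))


@pytest.fixture(scope="session")
def training_cohort():
    """A training-sized cohort merged with its true pool sizes."""
    cohort, truth = generate_cohort(CohortParams(n=367, seed=11))
    return cohort.merge(truth[["participant_id", "pool_g"]], on="participant_id")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
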