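import numpy as np
import pandas as pd
import pytest

from bennscale.anthropometry import derive_measures
from bennscale.cohort import (GeneratorParams, generate_cohort,
                              generate_mortality)


@pytest.fixture(scope="session")
def female_params():
    return GeneratorParams.female_defaults(n=2_000, seed=11)


@pytest.fixture(scope="session")
def female_cohort(female_params):
    """Small female-like cohort with derived measures and survival outcomes."""
    c = generate_mortality(generate_cohort(female_params), female_params)
    return derive_measures(c)


@pytest.fixture(scope="session")
def male_cohort():
    p = GeneratorParams.male_defaults(n=2_000, seed=12)
    return derive_measures(generate_mortality(generate_cohort(p), p))


@pytest.fixture(scope="session")
def mixed_cohort(female_cohort, male_cohort):
    return pd.concat([female_cohort, male_cohort], ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
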