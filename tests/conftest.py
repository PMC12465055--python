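import numpy as np
import pandas as pd
import pytest

from prostasim import (LifeTable, PopulationPyramid, SyntheticConfig,
                       make_population)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """Census-shaped pyramid and Gompertz life table for 50k men."""
    return make_population(SyntheticConfig(n_individuals=50_000))


@pytest.fixture()
def flat_pyramid():
    ages = np.arange(40, 101)
    return PopulationPyramid(2020, pd.Series(np.full(ages.size, 10.0), index=ages))


@pytest.fixture()
def zero_mortality():
    ages = np.arange(40, 101)
    return LifeTable(pd.Series(np.zeros(ages.size), index=ages))
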