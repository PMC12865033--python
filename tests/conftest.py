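import numpy as np
import pandas as pd
import pytest

from eqmap.synth import (
    PopulationConfig,
    SplitSpec,
    default_missingness_spec,
    generate_population,
    inject_missingness,
    split_stratified,
)


@pytest.fixture(scope="session")
def population() -> pd.DataFrame:
    """A mid-size complete synthetic survey shared across tests."""
    return generate_population(PopulationConfig(n=3000, seed=3))


@pytest.fixture(scope="session")
def big_population() -> pd.DataFrame:
    """Large sample for calibration-level checks (correlations, ceiling)."""
    return generate_population(PopulationConfig(n=20_000, seed=11))


@pytest.fixture(scope="session")
def missing_table(population) -> pd.DataFrame:
    return inject_missingness(population, default_missingness_spec(), seed=4)


@pytest.fixture(scope="session")
def survey_splits(missing_table):
    return split_stratified(missing_table, SplitSpec(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
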