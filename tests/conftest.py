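import numpy as np
import pandas as pd
import pytest

from necromap import synthetic as S


@pytest.fixture(scope="session")
def env80():
    """Default synthetic landscape environment: 80 sites."""
    return S.generate_environment(80, seed=1)


@pytest.fixture(scope="session")
def landscape(env80):
    """Default landscape: environment + phylotype table + ground truth."""
    table, truth = S.generate_phylotypes(env80, 100, seed=2)
    truth.mnc_coefficients = S.default_mnc_coefficients(truth.cluster_names())
    return env80, table, truth


@pytest.fixture(scope="session")
def true_cluster_abundance(landscape):
    env, table, truth = landscape
    return pd.DataFrame(
        {c: table[truth.members(c)].sum(axis=1) for c in truth.cluster_names()}
    ).reset_index(drop=True)


@pytest.fixture(scope="session")
def amino_sugars(landscape, true_cluster_abundance):
    env, table, truth = landscape
    return S.generate_amino_sugars(env, true_cluster_abundance, truth, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
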