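import numpy as np
import pandas as pd
import pytest

from rhizostab import simulate as sim
from rhizostab import stability as st


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 1)."""
    return sim.generate_study(sim.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_filtered(default_study):
    relab = st.to_relative_abundance(default_study.counts)
    return st.filter_by_mean_relab(relab)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_counts(rng, n_otus=20, n_samples=12, lam=50):
    """Random Poisson count table with generic ids."""
    X = rng.poisson(lam, size=(n_otus, n_samples))
    return pd.DataFrame(X, index=[f"O{i:03d}" for i in range(n_otus)],
                        columns=[f"S{j:02d}" for j in range(n_samples)])


@pytest.fixture()
def random_counts(rng):
    return make_counts(rng)
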