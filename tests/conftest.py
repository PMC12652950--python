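import logging

import pandas as pd
import pytest

from rewirenet import SimConfig, simulate_counts

logging.getLogger("rewirenet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulation under the default study conditions."""
    return simulate_counts(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulation for fast unit tests."""
    config = SimConfig(n_genes=600, n_tf=40, seed=3)
    return simulate_counts(config)


@pytest.fixture()
def group_columns():
    def _split(samples: pd.DataFrame):
        g1 = samples.loc[samples["group"] == "fertile", "sample"]
        g2 = samples.loc[samples["group"] == "subfertile", "sample"]
        return g1, g2

    return _split
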