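import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mirgsa as mg

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scenario():
    """One generated instance of the default study conditions."""
    sc = mg.SyntheticScenario(seed=3)
    stats, tm, sets, truth = mg.generate_scenario(sc)
    return sc, stats, tm, sets, truth


@pytest.fixture(scope="session")
def small_scenario():
    """A fast, reduced-size scenario with no planted signal."""
    sc = mg.SyntheticScenario(
        n_mirna=100,
        n_genes=500,
        targets_per_mirna=(2, 8),
        n_sets=50,
        set_size=(10, 30),
        planted_sets=(),
        seed=7,
    )
    return (sc, *mg.generate_scenario(sc))


def random_target_map(rng: np.random.Generator, n_mirna=10, n_genes=8):
    """A random bipartite target table with unit-ish weights."""
    rows = []
    for i in range(n_mirna):
        k = int(rng.integers(1, n_genes + 1))
        for g in rng.choice(n_genes, size=k, replace=False):
            rows.append((f"m{i}", f"g{g}", float(rng.uniform(0.1, 2.0))))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "weight"])
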