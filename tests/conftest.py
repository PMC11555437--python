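import numpy as np
import pytest

from omnik import CountTable, SampleMetadata
from omnik.simulation import default_dm_params, simulate_counts, synth_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 3, 1],
            [0, 2, 4, 0],
            [1, 1, 0, 6],
            [2, 0, 0, 2],
            [0, 3, 1, 1],
        ]
    )
    return CountTable(counts, [f"s{i}" for i in range(1, 6)], ["t1", "t2", "t3", "t4"])


@pytest.fixture
def sim_table_tree():
    """A moderately sized simulated community with its tree."""
    params = default_dm_params(p=30, seed=7)
    tree = synth_tree(30, 8)
    table = simulate_counts(params, 20, 9)
    return table, tree


@pytest.fixture
def gaussian_meta(rng):
    n = 20
    T = rng.binomial(1, 0.5, n).astype(float)
    Z = rng.normal(size=(n, 2))
    y = 1.0 + T + Z @ np.array([0.5, 0.5]) + rng.normal(size=n)
    return SampleMetadata(y, T, Z, "gaussian", [f"s{i}" for i in range(1, n + 1)])
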