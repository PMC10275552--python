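import math

import numpy as np
import pytest

from islandbd import (
    CladeRecord,
    IslandDataset,
    ModelParams,
    make_table1_fixture,
    make_toy_suite,
)


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture(seed=1)


@pytest.fixture(scope="session")
def toys():
    return make_toy_suite()


@pytest.fixture()
def small_dataset():
    """Two small clades on a young island; cheap for likelihood and fitting."""
    return IslandDataset(
        island_age=10.0,
        mainland_pool_M=20,
        clades=(
            CladeRecord("a", 1, "endemic_clade", 6.0, (3.0, 1.2)),
            CladeRecord("b", 2, "non_endemic_singleton", 2.5),
        ),
    )


@pytest.fixture()
def small_params():
    return ModelParams(lambda_c0=0.3, mu=0.1, K=8.0, gamma0=0.01, lambda_a=0.0)


def random_dataset(rng: np.random.Generator) -> IslandDataset:
    """A random valid dataset (used by round-trip property tests)."""
    T = float(rng.uniform(5.0, 40.0))
    M = int(rng.integers(5, 2000))
    n_clades = int(rng.integers(0, 6))
    ids = rng.choice(np.arange(1, M + 1), size=n_clades, replace=False)
    clades = []
    for i in range(n_clades):
        a = float(rng.uniform(0.01, 0.999) * T)
        size = int(rng.integers(1, 8))
        if size == 1:
            status = str(rng.choice(["non_endemic_singleton", "endemic_singleton"]))
            branch = ()
        else:
            status = "endemic_clade"
            branch = tuple(float(x) for x in rng.uniform(0.0, a, size - 1))
        clades.append(
            CladeRecord(f"c{i}", int(ids[i]), status, a, branch)
        )
    return IslandDataset(island_age=T, mainland_pool_M=M, clades=tuple(clades))
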