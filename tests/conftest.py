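import numpy as np
import pandas as pd
import pytest

from ecoassembly import OtuTable, SimConfig, simulate_dataset, tree_from_string


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """4 samples x 5 OTUs with assorted structure (shared, exclusive, rare)."""
    return pd.DataFrame(
        [
            [10, 5, 0, 1, 0],
            [10, 5, 3, 0, 0],
            [10, 0, 3, 0, 1],
            [10, 5, 3, 1, 0],
        ],
        index=["S1", "S2", "S3", "S4"],
        columns=["O1", "O2", "O3", "O4", "O5"],
    )


@pytest.fixture
def toy_table(toy_counts) -> OtuTable:
    return OtuTable(toy_counts)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); -> d(A,B)=2, d(A,C)=d(B,C)=4."""
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small neutral community reused by several test modules."""
    return simulate_dataset(
        SimConfig(n_otus=80, n_samples=8, depth=3000, regime="neutral", seed=101)
    )


def random_table(rng: np.random.Generator, n_samples: int = 6, n_otus: int = 12) -> OtuTable:
    counts = rng.integers(0, 40, size=(n_samples, n_otus))
    counts[:, 0] += 1  # guarantee positive row totals
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"O{j}" for j in range(n_otus)],
        )
    )
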