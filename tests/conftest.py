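import numpy as np
import pytest

import qsarforge as qf

#: The two bundled study models: response column -> descriptor subset.
RAF1_SUBSET = ("IW1", "FLEX")
V600E_SUBSET = ("ACDODO", "IW2", "DD8", "PSA")


@pytest.fixture(scope="session")
def table():
    return qf.load_descriptor_table()


@pytest.fixture(scope="session")
def raf1_dataset(table):
    return qf.build_qsar_dataset(table, "pIC50_RAF1", RAF1_SUBSET)


@pytest.fixture(scope="session")
def v600e_dataset(table):
    return qf.build_qsar_dataset(table, "pIC50_V600E", V600E_SUBSET)


def random_dataset(rng: np.random.Generator, n: int | None = None, p: int | None = None):
    """A small random regression dataset for property tests."""
    n = n or int(rng.integers(8, 30))
    p = p or int(rng.integers(1, min(5, n - 3) + 1))
    X = rng.normal(size=(n, p)) * rng.lognormal(sigma=1.0, size=p)
    beta = rng.normal(size=p)
    y = 5.0 + X @ beta + rng.normal(scale=0.3, size=n)
    names = [f"D{j + 1}" for j in range(p)]
    ids = [f"c{i + 1}" for i in range(n)]
    return qf.QsarDataset(ids, names, X, y)
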