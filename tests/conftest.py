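import numpy as np
import pandas as pd
import pytest

from lignevo import synth
from lignevo.coreio import read_newick


@pytest.fixture(scope="session")
def small_tree():
    """Hand-built 4-tip non-ultrametric tree used by the enumeration oracles."""
    return read_newick("((A:1,B:1):1,(C:1.5,D:0.5):0.5):0;")


@pytest.fixture(scope="session")
def balanced_tree():
    """Ultrametric 4-tip tree (root age 2)."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture(scope="session")
def star_tree_8():
    """8-tip star tree with unit branches: the C = I limit."""
    tips = ",".join(f"s{i}:1" for i in range(8))
    return read_newick(f"({tips}):0;")


@pytest.fixture(scope="session")
def yule_tree_20():
    return synth.simulate_tree(20, 100.0, seed=7)


@pytest.fixture(scope="session")
def two_cluster_data():
    """Two tight, far-apart clusters of 10 points each (perfectly separable)."""
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 0.3, size=(10, 3))
    b = rng.normal(20.0, 0.3, size=(10, 3))
    X = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2", "f3"],
                     index=[f"p{i}" for i in range(20)])
    y = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
    return X, y
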