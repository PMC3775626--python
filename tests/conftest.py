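import numpy as np
import pytest

from phylodiv.data_model import SampleCounts, read_newick
from phylodiv.synthetic import random_tree, toy_tree_T0


@pytest.fixture
def t0():
    """The canonical worked example: ((A:1,B:1):1,C:1) with counts {A:2,B:1,C:1}."""
    return toy_tree_T0()


@pytest.fixture
def star20():
    """20-leaf star tree with unit branch lengths."""
    labels = [f"T{i}" for i in range(20)]
    return read_newick("(" + ",".join(f"{lab}:1" for lab in labels) + ");")


def make_random_fixture(rng, min_leaves=2, max_leaves=12, max_total=40, min_total=1):
    """Random (tree, SampleCounts) pair; counts may include zeros."""
    n_leaves = int(rng.integers(min_leaves, max_leaves + 1))
    tree = random_tree(n_leaves, seed=int(rng.integers(2**31)))
    labels = tree.tip_labels
    total = int(rng.integers(min_total, max_total + 1))
    counts = rng.multinomial(total, rng.dirichlet(np.ones(n_leaves)))
    return tree, SampleCounts(dict(zip(labels, counts.tolist())))


@pytest.fixture
def random_fixture_factory():
    return make_random_fixture
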