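import numpy as np
import pandas as pd
import pytest

from phenosignal import parse_newick
from phenosignal.synthetic import simulate_tree


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_tree():
    # two clades of four, all tips at depth 3
    return parse_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


@pytest.fixture(scope="session")
def yule_tree_20():
    return simulate_tree(20, birth_rate=1.0, rng=11, height=1.0)


def random_trees(n_trees, n_tips, seed=0):
    gen = np.random.default_rng(seed)
    for _ in range(n_trees):
        yield simulate_tree(
            int(gen.integers(4, n_tips + 1)),
            birth_rate=1.0,
            rng=gen,
        )
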