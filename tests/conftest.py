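import numpy as np
import pandas as pd
import pytest

from phylodistricts import CommunityMatrix, read_newick
from phylodistricts.simulate import simulate_tree


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); — the 5-node worked example."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_landscape():
    """A 6-plot, 12-species landscape with two clade-confined halves."""
    tree = simulate_tree(12, seed=42)
    names = tree.tip_names
    rng = np.random.default_rng(7)
    counts = np.zeros((6, 12), dtype=int)
    for p in range(6):
        # plots 0-2 live in the first half of the tip order, 3-5 in the second
        lo, hi = (0, 6) if p < 3 else (6, 12)
        chosen = rng.choice(np.arange(lo, hi), size=4, replace=False)
        counts[p, chosen] = rng.integers(1, 6, size=4)
    cm = CommunityMatrix(
        pd.DataFrame(counts, index=[f"p{i}" for i in range(6)], columns=names)
    )
    return tree, cm


def random_tree(n_tips: int, seed: int):
    """Random ultrametric tree via the package's Yule simulator."""
    return simulate_tree(n_tips, seed=seed)


def random_abundances(tree, seed: int, max_count: int = 5) -> dict:
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(1, max_count + 1)) for name in tree.tip_names}
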