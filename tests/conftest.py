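import numpy as np
import pytest

from traitdiv.simulate import yule_tree
from traitdiv.tree import TimeTree, read_tree


@pytest.fixture(scope="session")
def tree3():
    return read_tree("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture(scope="session")
def tree4():
    return read_tree("((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def tree6():
    return read_tree(
        "(((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5):1.0,(E:2.0,F:2.0):1.0);"
    )


@pytest.fixture(scope="session")
def yule64():
    return yule_tree(64, rng=1001)


@pytest.fixture(scope="session")
def yule128():
    return yule_tree(128, rng=1002)


def star_tree(n: int, depth: float = 1.0) -> TimeTree:
    """Star phylogeny: n tips hanging off a single root at equal depth."""
    parent = np.full(n + 1, n, dtype=np.int64)
    parent[n] = -1
    brlen = np.full(n + 1, depth)
    brlen[n] = 0.0
    labels = [f"t{i+1}" for i in range(n)]
    return TimeTree(parent, brlen, labels, n_tips=n)


@pytest.fixture(scope="session")
def star16():
    return star_tree(16)
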