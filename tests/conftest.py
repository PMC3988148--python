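import numpy as np
import pytest

from chronodiv.chronogram import parse_chronogram
from chronodiv.simulate import simulate_yule

BALANCED4 = "((A:1,B:1):2,(C:2.5,D:2.5):0.5);"
CATERPILLAR4 = "(((A:1,B:1):1,C:2):1,D:3);"


def caterpillar_newick(n: int) -> str:
    nw = "A1:1"
    for i in range(2, n + 1):
        nw = f"({nw},A{i}:{i - 1}):1"
    return nw[:-2] + ";"


@pytest.fixture
def balanced4():
    return parse_chronogram(BALANCED4)


@pytest.fixture
def caterpillar4():
    return parse_chronogram(CATERPILLAR4)


@pytest.fixture
def yule_trees():
    """A small bank of seeded pure-birth trees of assorted sizes."""
    rng = np.random.default_rng(20240901)
    return [
        simulate_yule(n, lam, seed=int(rng.integers(2**31)))
        for n, lam in [(8, 1.0), (20, 0.5), (30, 1.5), (50, 0.3), (74, 1.0)]
    ]
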