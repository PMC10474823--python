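import numpy as np
import pytest

import wingplan as wp

# 8-tip ultrametric tree (all tip depths 3) used across PGLS tests
ULTRAMETRIC_NEWICK = (
    "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,((E:1,F:1):1,(G:1.5,H:1.5):0.5):1);"
)


@pytest.fixture(scope="session")
def ultrametric_tree():
    return wp.Phylogeny.from_newick(ULTRAMETRIC_NEWICK)


@pytest.fixture
def rng():
    return np.random.default_rng(20230902)


def random_geometries(rng, n):
    """n random valid (WL, S1, WS, f) tuples spanning realistic bird sizes."""
    wl = rng.uniform(3.0, 40.0, n)
    s1 = wl * rng.uniform(0.25, 0.9, n)
    ws = 2.0 * wl * rng.uniform(1.0, 2.2, n)
    f = rng.uniform(0.0, 1.0, n)
    return np.column_stack([wl, s1, ws, f])
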