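import numpy as np
import pytest

from ltn.tree import BinaryTaxonomyTree, random_binary_tree


@pytest.fixture(scope="session")
def balanced4():
    return BinaryTaxonomyTree.from_nested((("u1", "u2"), ("u3", "u4")))


@pytest.fixture(scope="session")
def caterpillar4():
    return BinaryTaxonomyTree.from_nested(("u1", ("u2", ("u3", "u4"))))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_positive_composition(rng, K):
    p = rng.dirichlet(np.full(K, 2.0))
    return np.maximum(p, 1e-9) / np.maximum(p, 1e-9).sum()


@pytest.fixture(scope="session")
def tree_pool():
    """A small pool of random binary trees of varied size."""
    return [random_binary_tree(K, seed=K * 13 + 1) for K in (3, 5, 8, 12, 20)]
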