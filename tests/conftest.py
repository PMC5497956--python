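import numpy as np
import pytest

from mmgg import ConstraintSet, Network, Partition


@pytest.fixture
def two_clique_network():
    """Two 10-cliques joined by a single bridge edge, with its planted labels."""
    a = np.zeros((20, 20))
    a[:10, :10] = 1.0
    a[10:, 10:] = 1.0
    np.fill_diagonal(a, 0.0)
    a[0, 10] = a[10, 0] = 1.0
    truth = Partition(np.array([1] * 10 + [2] * 10), 2)
    return Network(a), truth


@pytest.fixture
def triangle_target():
    """3-node rank-1 factorization problem: O = W = all-ones off-diagonal."""
    from mmgg import WeightedTarget

    return WeightedTarget(np.ones((3, 3)) - np.eye(3))


def random_instance(rng, n=8, k=3, p_edge=0.4):
    """A random symmetric (W, O) pair with mixed weights for solver tests."""
    from mmgg import WeightedTarget

    o = (rng.random((n, n)) < p_edge).astype(float)
    o = np.triu(o, 1)
    o = o + o.T
    w = rng.uniform(0.2, 5.0, size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return WeightedTarget.from_dense(w, o)
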