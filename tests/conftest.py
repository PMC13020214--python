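import numpy as np
import pytest

from sapling.trees import ReadCountData, make_tree


@pytest.fixture
def chain3():
    """1 -> 2 -> 3."""
    return make_tree({2: 1, 3: 2})


@pytest.fixture
def star3():
    """1 -> {2, 3}."""
    return make_tree({2: 1, 3: 1})


@pytest.fixture
def data_90_40_40():
    """Single sample, depths 100, variant reads (90, 40, 40).

    Naive frequencies (0.9, 0.4, 0.4): mutation 1 is clearly ancestral and
    mutations 2, 3 are interchangeable, so three trees tie at the optimum.
    """
    return ReadCountData(["s1"], [1, 2, 3], [[90, 40, 40]], [[100, 100, 100]])


def random_parent_vector(rng: np.random.Generator, n: int) -> list:
    """A random rooted labeled tree as a parent vector (root = index 0)."""
    return [-1] + [int(rng.integers(0, i)) for i in range(1, n)]


def tree_from_parent_vector(par, labels=None):
    labels = labels if labels is not None else list(range(len(par)))
    pmap = {labels[j]: labels[p] for j, p in enumerate(par) if p >= 0}
    return make_tree(pmap, nodes=labels)
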