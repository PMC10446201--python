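import itertools

import numpy as np
import pytest

from rewirenet import SpatialDigraph, generate_random_digraph, make_fixture


@pytest.fixture
def two_node():
    return make_fixture("two-node-single-edge")


@pytest.fixture
def three_cycle():
    return make_fixture("three-cycle")


@pytest.fixture
def cdu_minimal():
    return make_fixture("cdu-minimal")


@pytest.fixture
def two_cliques():
    return make_fixture("two-cliques")


@pytest.fixture
def complete4():
    return make_fixture("complete-4")


@pytest.fixture
def study_graph():
    """Random n=100, m=912 digraph under the default weight model."""
    return generate_random_digraph(100, 912, rng=12345)


def random_small_graph(rng, n_max=10, n_min=2):
    """Random small digraph with positive weights for oracle cross-checks."""
    n = int(rng.integers(n_min, n_max + 1))
    max_m = n * (n - 1)
    m = int(rng.integers(1, max_m + 1))
    return generate_random_digraph(n, m, rng=rng)


def all_digraphs(n):
    """Every labelled loopless digraph on n nodes, unit weights."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    coords = np.zeros((n, 2))
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        a = np.zeros((n, n))
        for bit, (i, j) in zip(bits, pairs):
            if bit:
                a[j, i] = 1.0  # edge i -> j
        yield SpatialDigraph(a, coords.copy())
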