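import itertools

import networkx as nx
import numpy as np
import pytest

from quarnet.networks import SemiDirectedNetwork


def make_cycle_network(taxa, retic_index=0):
    """Single cycle spanning all taxa (in the given order), one pendant leaf
    per cycle vertex, reticulation below taxa[retic_index]."""
    s = len(taxa)
    und, dire, labels = [], [], {}
    for i, t in enumerate(taxa):
        und.append((f"c{i}", f"l{i}"))
        labels[f"l{i}"] = t
    for i in range(s):
        j = (i + 1) % s
        if i == retic_index or j == retic_index:
            dire.append((f"c{i}" if j == retic_index else f"c{j}",
                         f"c{retic_index}"))
        else:
            und.append((f"c{i}", f"c{j}"))
    return SemiDirectedNetwork.from_edges(und, dire, labels)


def make_caterpillar(taxa):
    """Unrooted caterpillar tree: cherry (t1, t2), then t3, t4, ..."""
    n = len(taxa)
    und, labels = [], {}
    for i, t in enumerate(taxa):
        labels[f"l{i}"] = t
    und.append(("i0", "l0"))
    und.append(("i0", "l1"))
    for i in range(2, n - 1):
        und.append((f"i{i-2}", f"i{i-1}"))
        und.append((f"i{i-1}", f"l{i}"))
    und.append((f"i{n-3}", f"l{n-1}"))
    return SemiDirectedNetwork.from_edges(und, [], labels)


@pytest.fixture
def cycle4():
    return make_cycle_network(list("abcd"))


@pytest.fixture
def cycle5():
    return make_cycle_network(list("abcde"))


@pytest.fixture
def cat5():
    return make_caterpillar([f"t{i}" for i in range(1, 6)])


@pytest.fixture
def cat6():
    return make_caterpillar([f"t{i}" for i in range(1, 7)])


@pytest.fixture(scope="session")
def random_networks():
    """A shared pool of small random networks for property tests."""
    from quarnet.simulate import random_network

    rng = np.random.default_rng(2024)
    nets = []
    for _ in range(12):
        n = int(rng.integers(5, 9))
        nets.append(random_network(n, int(rng.integers(2**31))))
    return nets
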