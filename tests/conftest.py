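import numpy as np
import pytest

from ecodecnet import (
    Link,
    NodeSpec,
    build_network,
    default_node_registry,
    generate_synthetic_community,
)


def matching_network(k: int, weight: float = 1.0):
    """One-to-one perfect matching: k sources each feeding its own sink."""
    nodes = [NodeSpec(f"a{i}") for i in range(k)] + [
        NodeSpec(f"b{i}") for i in range(k)
    ]
    links = [Link(f"a{i}", f"b{i}", weight) for i in range(k)]
    return build_network(nodes, links)


def star_network(leaves: int = 4, weight: float = 1.0):
    """One hub feeding every leaf with equal weight."""
    nodes = [NodeSpec("hub")] + [NodeSpec(f"leaf{i}") for i in range(leaves)]
    links = [Link("hub", f"leaf{i}", weight) for i in range(leaves)]
    return build_network(nodes, links)


def chain_network(w1: float = 0.8, w2: float = 0.2):
    """Three-node chain A -> B -> C with the given weights."""
    nodes = [NodeSpec("A"), NodeSpec("B"), NodeSpec("C")]
    return build_network(nodes, [Link("A", "B", w1), Link("B", "C", w2)])


def random_small_network(rng: np.random.Generator, max_n: int = 8):
    """A random non-degenerate digraph with n <= max_n, for oracle checks."""
    while True:
        n = int(rng.integers(2, max_n + 1))
        density = rng.uniform(0.2, 0.9)
        mask = rng.uniform(0, 1, (n, n)) < density
        weights = rng.uniform(0, 1, (n, n)) * mask
        if weights.sum() > 0:
            break
    nodes = [NodeSpec(f"x{i}") for i in range(n)]
    links = [
        Link(f"x{i}", f"x{j}", float(weights[i, j]))
        for i in range(n)
        for j in range(n)
        if weights[i, j] > 0
    ]
    return build_network(nodes, links), weights


@pytest.fixture(scope="session")
def registry():
    return default_node_registry()


@pytest.fixture(scope="session")
def synthetic_community():
    """One seeded synthetic fixture: (raw score table, assembled network)."""
    return generate_synthetic_community(seed=0)
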