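import numpy as np
import pytest

import oncopath as op


@pytest.fixture
def triangle_net():
    """Bidirectional triangle on genes 1-3 (physical)."""
    return op.direct_physical_edges([(1, 2), (2, 3), (3, 1)])


@pytest.fixture
def chain_net():
    """Directed chain 1 -> 2 -> 3 (regulatory)."""
    return op.InteractionNetwork(
        [op.Interaction(1, 2, "regulatory"), op.Interaction(2, 3, "regulatory")]
    )


def random_typed_network(n, p, seed, itypes=("physical", "regulatory", "metabolic")):
    """Erdos–Renyi-style directed typed network for oracle tests."""
    rng = np.random.default_rng(seed)
    net = op.InteractionNetwork()
    for g in range(1, n + 1):
        net.add_node(g)
    for a in range(1, n + 1):
        for b in range(1, n + 1):
            if a != b and rng.random() < p:
                net.add(op.Interaction(a, b, itypes[rng.integers(len(itypes))]))
    return net


@pytest.fixture
def small_scored(request):
    """A 30-node random network with deterministic pseudo-random OP scores."""
    net = random_typed_network(30, 0.12, seed=42)
    rng = np.random.default_rng(7)
    edges = sorted(net.simple_edges())
    opmap = dict(zip(edges, rng.uniform(0.0, 1.0, len(edges)).round(4)))
    return op.ScoredNetwork(net, opmap)
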