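import numpy as np
import pytest

from cnatree.data_model import CNATree, Event


@pytest.fixture
def example_tree() -> CNATree:
    """The worked five-node tree: T=(0,1,2,2,1), V=(+S1+S2, +S2+S3, -S1, -S4, +S1).

    Diploid root over five segments; node 5 (root -> 1 -> 5) carries genotype
    (4,3,2,2,2).
    """
    return CNATree(
        parents=(0, 1, 2, 2, 1),
        events=(
            Event({0: 1, 1: 1}),
            Event({1: 1, 2: 1}),
            Event({0: -1}),
            Event({3: -1}),
            Event({0: 1}),
        ),
        root_ploidy=(2, 2, 2, 2, 2),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_valid_tree(rng, n_max=6, k_max=5, delta_max=2):
    """Small random valid tree for property tests (rejection sampled)."""
    from cnatree.data_model import validate_tree

    while True:
        n = int(rng.integers(1, n_max + 1))
        K = int(rng.integers(2, k_max + 1))
        parents = [int(rng.integers(i)) for i in range(1, n + 1)]
        events = []
        for _ in range(n):
            k = int(rng.integers(1, min(3, K) + 1))
            segs = rng.choice(K, size=k, replace=False)
            deltas = {
                int(s): int(rng.integers(1, delta_max + 1))
                * (1 if rng.random() < 0.5 else -1)
                for s in segs
            }
            events.append(Event(deltas))
        tree = CNATree(parents, events, (2,) * K)
        if validate_tree(tree)[0]:
            return tree
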