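import numpy as np
import pytest

from dollophy import ErrorRates, Gain, Loss, PhyloTree, SCSMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rates():
    return ErrorRates(alpha=0.1, beta=0.01)


def random_scs(rng, n_cells, n_mutations, p_one=0.35, p_missing=0.1) -> SCSMatrix:
    entries = (rng.random((n_cells, n_mutations)) < p_one).astype(np.int8)
    entries[rng.random((n_cells, n_mutations)) < p_missing] = 2
    return SCSMatrix(entries)


def random_dollo1_tree(rng, n_mutations=6, max_losses=2) -> PhyloTree:
    """Random Dollo(1) tree: every mutation gained once, some lost once."""
    tree = PhyloTree()
    nodes = [tree.root]
    for m in rng.permutation(n_mutations):
        parent = nodes[int(rng.integers(len(nodes)))]
        nodes.append(tree.add_node(Gain(int(m)), parent))
    n_loss = int(rng.integers(max_losses + 1))
    lost: set[int] = set()
    for _ in range(n_loss):
        candidates = [
            (n, m)
            for n in tree.nodes()
            for m in tree.node_state(n)
            if m not in lost
        ]
        if not candidates:
            break
        n, m = candidates[int(rng.integers(len(candidates)))]
        tree.add_node(Loss(int(m), 1), n)
        lost.add(m)
    return tree


@pytest.fixture
def scs_factory():
    return random_scs


@pytest.fixture
def tree_factory():
    return random_dollo1_tree
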