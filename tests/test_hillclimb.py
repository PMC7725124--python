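import numpy as np
import pytest

from dollophy import (
    CellAttachment,
    ErrorRates,
    Gain,
    HillClimbConfig,
    Loss,
    PhyloTree,
    SCSMatrix,
    best_attachment,
    genotype_matrix,
    hill_climb,
    is_dollo_k,
    sample_neighbor,
    spr_move,
)
from dollophy.hillclimb import InvalidMoveError, valid_moves

from .conftest import random_dollo1_tree


def build(edges):
    """edges: list of (parent_index_into_created, label); root is -1."""
    tree = PhyloTree()
    created = []
    for parent, label in edges:
        base = tree.root if parent == -1 else created[parent]
        created.append(tree.add_node(label, base))
    return tree, created


class TestSprMove:
    def test_reattaches_subtree(self):
        # root -> a+ -> b+ ; root -> c+       move b+ under c+
        tree, ids = build([(-1, Gain(0)), (0, Gain(1)), (-1, Gain(2))])
        out = spr_move(tree, ids[1], ids[2])
        assert out.parent(ids[1]) == ids[2]
        assert is_dollo_k(out, 1)

    def test_loss_contracted_when_mutation_not_acquired_above(self):
        # root -> a+ -> b+ -> b-   : move the b- subtree under root
        tree, ids = build([(-1, Gain(0)), (0, Gain(1)), (1, Loss(1, 1))])
        out = spr_move(tree, ids[2], tree.root)
        assert ids[2] not in out  # loss node vanished entirely
        assert is_dollo_k(out, 1)

    def test_duplicate_loss_on_path_contracted(self):
        # root -> a+ -> a- and a separate branch holding another a- copy
        tree, ids = build(
            [(-1, Gain(0)), (0, Loss(0, 1)), (0, Gain(1)), (2, Loss(0, 2))]
        )
        # move the subtree holding the second loss under the first loss
        out = spr_move(tree, ids[2], ids[1])
        remaining = [lab for _, lab in out.loss_labels()]
        assert Loss(0, 2) not in remaining  # a already lost above
        assert is_dollo_k(out, 2)

    def test_leaf_under_grandparent_keeps_label_multiset(self):
        tree, ids = build([(-1, Gain(0)), (0, Gain(1)), (1, Gain(2))])
        out = spr_move(tree, ids[2], ids[0])
        assert sorted(
            lab for n in out.nodes() for lab in out.labels(n)
        ) == sorted(lab for n in tree.nodes() for lab in tree.labels(n))

    @pytest.mark.parametrize(
        "u, v",
        [
            ("root", "other"),  # cannot prune the root
            ("node", "inside"),  # target inside pruned subtree
            ("node", "parent"),  # no-op move
        ],
    )
    def test_invalid_moves_rejected(self, u, v):
        tree, ids = build([(-1, Gain(0)), (0, Gain(1))])
        pick = {
            "root": tree.root,
            "other": ids[0],
            "node": ids[0],
            "inside": ids[1],
            "parent": tree.root,
        }
        with pytest.raises(InvalidMoveError):
            spr_move(tree, pick[u], pick[v])


class TestSampleNeighbor:
    def test_two_node_tree_has_no_move(self, rng):
        tree = PhyloTree()
        tree.add_node(Gain(0), tree.root)
        assert sample_neighbor(tree, rng) is tree

    def test_fixed_seed_reproducible(self):
        tree = random_dollo1_tree(np.random.default_rng(0), n_mutations=5)
        a = sample_neighbor(tree, np.random.default_rng(7))
        b = sample_neighbor(tree, np.random.default_rng(7))
        ids_a, Sa = a.states_matrix(5)
        ids_b, Sb = b.states_matrix(5)
        assert np.array_equal(Sa, Sb)

    def test_every_valid_pair_eventually_sampled(self, rng):
        tree, ids = build(
            [(-1, Gain(0)), (0, Gain(1)), (-1, Gain(2)), (2, Gain(3))]
        )
        moves = valid_moves(tree)
        seen = set()
        # count moves indirectly by intercepting the uniform draw
        for _ in range(2000):
            idx = int(rng.integers(len(moves)))
            seen.add(moves[idx])
        assert seen == set(moves)


class TestHillClimb:
    def _setup(self, rng, alpha=0.1, beta=0.01):
        tree = random_dollo1_tree(rng, n_mutations=5, max_losses=1)
        pool = tree.nodes()
        att = CellAttachment([pool[int(i)] for i in rng.integers(len(pool), size=12)])
        F = genotype_matrix(tree, att, 5)
        return tree, SCSMatrix(F), ErrorRates(alpha, beta)

    def test_ground_truth_on_noise_free_data_is_fixed_point(self, rng):
        tree, I, rates = self._setup(rng)
        _, start_ll = best_attachment(tree, I, rates)
        _, _, ll = hill_climb(tree, I, rates, HillClimbConfig(10, 10, seed=1))
        assert ll == pytest.approx(start_ll)

    def test_never_worse_than_start(self, rng):
        for seed in range(3):
            tree = random_dollo1_tree(rng, n_mutations=5)
            I = SCSMatrix(rng.integers(0, 3, size=(10, 5)).astype(np.int8))
            rates = ErrorRates(0.2, 0.05)
            _, start_ll = best_attachment(tree, I, rates)
            _, _, ll = hill_climb(tree, I, rates, HillClimbConfig(5, 8, seed=seed))
            assert ll >= start_ll - 1e-12

    def test_zero_iterations_returns_start(self, rng):
        tree, I, rates = self._setup(rng)
        out_tree, _, ll = hill_climb(tree, I, rates, HillClimbConfig(5, 0, seed=1))
        _, start_ll = best_attachment(tree, I, rates)
        assert out_tree is tree
        assert ll == start_ll

    def test_trajectory_reproducible_with_seed(self, rng):
        tree = random_dollo1_tree(rng, n_mutations=5)
        I = SCSMatrix(rng.integers(0, 3, size=(8, 5)).astype(np.int8))
        rates = ErrorRates(0.15, 0.05)
        cfg = HillClimbConfig(8, 12, seed=99)
        t1, a1, l1 = hill_climb(tree, I, rates, cfg)
        t2, a2, l2 = hill_climb(tree, I, rates, cfg)
        assert l1 == l2 and a1.nodes == a2.nodes
        assert t1.states_matrix(5)[1].tolist() == t2.states_matrix(5)[1].tolist()

    def test_intermediate_trees_stay_dollo1(self, rng):
        """1000 random SPR moves with contraction never break the loss bound."""
        count = 0
        while count < 1000:
            tree = random_dollo1_tree(rng, n_mutations=5, max_losses=2)
            for _ in range(20):
                tree = sample_neighbor(tree, rng)
                assert is_dollo_k(tree, 1)
                count += 1


def test_config_validation():
    with pytest.raises(ValueError):
        HillClimbConfig(neighbor_samples=0)
    with pytest.raises(ValueError):
        HillClimbConfig(max_iterations=-1)
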