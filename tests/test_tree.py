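import numpy as np
import pytest

from dollophy import (
    CellAttachment,
    ErrorRates,
    ExtendedMatrix,
    Gain,
    Loss,
    PhyloTree,
    SCSMatrix,
    best_attachment,
    genotype_matrix,
    is_dollo_k,
    read_dot,
    to_dot,
    tree_from_extended_matrix,
)
from dollophy.extended import check_dollo_completion, extended_columns
from dollophy.tree import extended_matrix_from_tree

from .conftest import random_dollo1_tree
from .oracles import entry_ll_table


def chain_tree(*labels) -> PhyloTree:
    tree = PhyloTree()
    cur = tree.root
    for lab in labels:
        cur = tree.add_node(lab, cur)
    return tree


class TestNodeState:
    def test_root_state_is_empty(self):
        assert PhyloTree().node_state(0) == frozenset()

    def test_gain_then_loss_cancels(self):
        t = chain_tree(Gain(0), Gain(1), Loss(1, 1))
        assert t.node_state(3) == frozenset({0})

    def test_gain_chain_accumulates(self):
        t = chain_tree(Gain(0), Gain(1), Gain(2))
        assert t.node_state(3) == frozenset({0, 1, 2})

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            PhyloTree().node_state(99)

    def test_same_node_gain_and_loss_cancel(self):
        t = PhyloTree()
        n = t.add_node([Gain(0), Loss(0, 1)], t.root)
        assert t.node_state(n) == frozenset()


class TestTreeFromExtendedMatrix:
    def test_states_reproduce_rows(self):
        """Synthetic Dollo(2) completion: per-row states equal the genotypes."""
        E = ExtendedMatrix(
            columns=extended_columns(2, 2),
            entries=np.array(
                [[1, 0, 0, 0, 0, 0], [1, 0, 0, 1, 0, 0], [1, 0, 0, 1, 1, 0]],
                dtype=np.int8,
            ),
        )
        tree, row_nodes = tree_from_extended_matrix(E, return_row_nodes=True)
        expected = [{0}, {0, 1}, {0}]
        for r, node in enumerate(row_nodes):
            assert tree.node_state(node) == frozenset(expected[r])

    def test_identity_matrix_gives_star(self):
        E = ExtendedMatrix(extended_columns(3, 0), np.eye(3, dtype=np.int8))
        tree = tree_from_extended_matrix(E)
        kids = tree.children(tree.root)
        assert len(kids) == 3 and all(not tree.children(k) for k in kids)

    def test_all_zero_matrix_gives_root_only(self):
        E = ExtendedMatrix(extended_columns(2, 1), np.zeros((3, 4), dtype=np.int8))
        assert len(tree_from_extended_matrix(E)) == 1

    def test_identical_columns_merge_on_one_node(self):
        M = np.array([[1, 1], [1, 1], [0, 0]], dtype=np.int8)
        tree = tree_from_extended_matrix(ExtendedMatrix(extended_columns(2, 0), M))
        assert len(tree) == 2
        assert set(tree.labels(1)) == {Gain(0), Gain(1)}

    def test_conflicting_matrix_rejected(self):
        M = np.array([[0, 1], [1, 0], [1, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="conflict"):
            tree_from_extended_matrix(ExtendedMatrix(extended_columns(2, 0), M))

    def test_round_trip_satisfies_dollo_and_linking(self, rng):
        """Extraction then re-expansion reproduces the completed matrix rows."""
        for _ in range(20):
            tree = random_dollo1_tree(rng, n_mutations=5, max_losses=2)
            pool = tree.nodes()
            att = CellAttachment(
                [pool[int(i)] for i in rng.integers(len(pool), size=8)]
            )
            E = extended_matrix_from_tree(tree, att, 5, 1)
            F = genotype_matrix(tree, att, 5)
            assert check_dollo_completion(E, SCSMatrix(F), F)
            back = tree_from_extended_matrix(E)
            assert is_dollo_k(back, 1)
            back_att, _ = best_attachment(back, SCSMatrix(F), ErrorRates(0.01, 0.01))
            assert np.array_equal(genotype_matrix(back, back_att, 5), F)


class TestGenotypeMatrix:
    def test_all_cells_at_root_all_zero(self):
        t = chain_tree(Gain(0))
        F = genotype_matrix(t, CellAttachment([0, 0, 0]), 1)
        assert not F.any()

    def test_rows_are_node_states(self):
        t = chain_tree(Gain(0), Gain(1), Loss(0, 1))
        F = genotype_matrix(t, CellAttachment([1, 2, 3]), 2)
        assert F.tolist() == [[1, 0], [1, 1], [0, 1]]


class TestBestAttachment:
    def test_noise_free_recovers_states(self, rng):
        tree = random_dollo1_tree(rng, n_mutations=4)
        pool = tree.nodes()
        att = CellAttachment([pool[int(i)] for i in rng.integers(len(pool), size=6)])
        F = genotype_matrix(tree, att, 4)
        got_att, ll = best_attachment(tree, SCSMatrix(F), ErrorRates(0.05, 0.01))
        assert np.array_equal(genotype_matrix(tree, got_att, 4), F)

    def test_root_only_tree(self):
        I = SCSMatrix(np.array([[1, 0], [0, 0]], dtype=np.int8))
        att, ll = best_attachment(PhyloTree(), I, ErrorRates(0.1, 0.01))
        assert att.nodes == [0, 0]
        expected = sum(
            entry_ll_table(int(I.entries[c, m]), 0, 0.1, 0.01)
            for c in range(2)
            for m in range(2)
        )
        assert ll == pytest.approx(expected)

    def test_matches_exhaustive_per_cell_scan(self, rng):
        tree = chain_tree(Gain(0), Gain(1), Gain(2))
        I = SCSMatrix(rng.integers(0, 3, size=(2, 3)).astype(np.int8))
        alpha, beta = 0.1, 0.1
        att, ll = best_attachment(tree, I, ErrorRates(alpha, beta))
        ids, S = tree.states_matrix(3)
        total = 0.0
        for c in range(2):
            scores = [
                sum(
                    entry_ll_table(int(I.entries[c, m]), int(S[x, m]), alpha, beta)
                    for m in range(3)
                )
                for x in range(len(ids))
            ]
            best = int(np.argmax(scores))
            assert att[c] == ids[best]
            total += scores[best]
        assert ll == pytest.approx(total)

    def test_dominates_any_fixed_attachment(self, rng):
        tree = random_dollo1_tree(rng, n_mutations=4)
        I = SCSMatrix(rng.integers(0, 3, size=(5, 4)).astype(np.int8))
        rates = ErrorRates(0.1, 0.02)
        _, best_ll = best_attachment(tree, I, rates)
        pool = tree.nodes()
        for _ in range(10):
            att = CellAttachment([pool[int(i)] for i in rng.integers(len(pool), size=5)])
            F = genotype_matrix(tree, att, 4)
            from dollophy import matrix_log_likelihood

            assert best_ll >= matrix_log_likelihood(I, F, rates) - 1e-9


class TestIsDolloK:
    def test_two_gains_of_same_mutation_rejected(self):
        t = PhyloTree()
        t.add_node(Gain(0), t.root)
        t.add_node(Gain(0), t.root)
        assert not is_dollo_k(t, 1)

    def test_loss_count_against_k(self):
        t = PhyloTree()
        a = t.add_node(Gain(0), t.root)
        b = t.add_node(Gain(1), a)
        c = t.add_node(Gain(2), a)
        t.add_node(Loss(0, 1), b)
        t.add_node(Loss(0, 2), c)
        assert not is_dollo_k(t, 1)
        assert is_dollo_k(t, 2)

    def test_loss_above_gain_rejected(self):
        t = chain_tree(Loss(0, 1), Gain(0))
        assert not is_dollo_k(t, 1)

    def test_double_loss_on_one_path_rejected(self):
        t = chain_tree(Gain(0), Loss(0, 1), Loss(0, 2))
        assert not is_dollo_k(t, 2)


class TestDot:
    def test_root_only(self):
        text = to_dot(PhyloTree())
        assert text.startswith("digraph") and 'label="germline"' in text

    def test_loss_node_styled_red(self):
        t = chain_tree(Gain(0), Loss(0, 1))
        text = to_dot(t)
        assert "indianred1" in text

    def test_collapse_merges_five_gain_chain(self):
        t = chain_tree(*(Gain(i) for i in range(5)))
        text = to_dot(t, collapse_linear_paths=True)
        node_lines = [l for l in text.splitlines() if "label=" in l]
        assert len(node_lines) == 2  # germline + one merged display node
        assert "mut1, mut2, mut3, mut4, mut5" in text

    def test_read_dot_round_trip(self, tmp_path, rng):
        tree = random_dollo1_tree(rng, n_mutations=4, max_losses=1)
        p = tmp_path / "t.gv"
        p.write_text(to_dot(tree))
        back, names = read_dot(p)
        assert names == [f"mut{i}" for i in range(1, 5)]
        ids_a, Sa = tree.states_matrix(4)
        ids_b, Sb = back.states_matrix(4)
        assert sorted(map(tuple, Sa)) == sorted(map(tuple, Sb))
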