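"""Randomized hill-climbing refinement over Subtree-Prune-and-Reattach moves.

The ILP incumbent under a timeout can be suboptimal, so the search continues
locally in tree space: a *neighbor* of a tree is obtained by pruning the
subtree rooted at a node ``u`` and reattaching it as a child of a node ``v``
outside that subtree.  Loss nodes invalidated by the move (their mutation is
no longer acquired above them, or was already lost higher on the path) are
contracted away, which can only remove losses and therefore preserves the
Dollo(k) property.  The full SPR neighborhood is quadratic in tree size, so
each iteration scores only ``neighbor_samples`` random neighbors and moves
to the best one when it strictly improves the current score; the best
tree/attachment ever seen is returned after ``max_iterations`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .error_model import ErrorRates
from .extended import Gain, Loss
from .matrix import SCSMatrix
from .tree import CellAttachment, PhyloTree, best_attachment


@dataclass
class HillClimbConfig:
    neighbor_samples: int = 30  # random SPR neighbors scored per iteration
    max_iterations: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.neighbor_samples < 1 or self.max_iterations < 0:
            raise ValueError("neighbor_samples must be >= 1 and max_iterations >= 0")


class InvalidMoveError(ValueError):
    """The (u, v) pair does not describe a legal SPR move."""


def _contract_invalid_losses(tree: PhyloTree) -> None:
    """Drop every loss label whose mutation is not active just above it.

    One preorder sweep tracking the running state handles both failure
    modes: the gain is missing above (or sits below), or another loss of
    the same mutation already fired on the path.  A node whose labels all
    turn out to be invalid losses is contracted away entirely; children
    inherit the unchanged state, exactly as after the contraction.
    """
    to_contract: list[int] = []
    stack: list[tuple[int, frozenset[int]]] = [(tree.root, frozenset())]
    while stack:
        node, state = stack.pop()
        st = set(state)
        labels = tree.labels(node)
        kept: list = []
        for lab in labels:  # gains first: a same-node gain+loss pair is legal
            if isinstance(lab, Gain):
                st.add(lab.mutation)
                kept.append(lab)
        for lab in labels:
            if isinstance(lab, Loss):
                if lab.mutation in st:
                    st.discard(lab.mutation)
                    kept.append(lab)
        if len(kept) != len(labels):
            if kept:
                tree.set_labels(node, kept)
            else:
                to_contract.append(node)  # had labels, all invalid losses
        for kid in tree.children(node):
            stack.append((kid, frozenset(st)))
    for node in to_contract:
        tree.contract(node)


def spr_move(tree: PhyloTree, u: int, v: int) -> PhyloTree:
    """Prune the subtree at ``u`` and reattach it as a child of ``v``.

    Returns a new tree; invalidated loss nodes anywhere in the result are
    contracted, so the output satisfies the same Dollo(k) bound as the input.
    """
    if u not in tree or v not in tree:
        raise InvalidMoveError(f"unknown node in move ({u}, {v})")
    if u == tree.root:
        raise InvalidMoveError("cannot prune the root")
    if v in tree.subtree_nodes(u):
        raise InvalidMoveError("target lies inside the pruned subtree")
    if v == tree.parent(u):
        raise InvalidMoveError("move is a no-op: target is already the parent")
    out = tree.copy()
    out.detach(u)
    out.attach(u, v)
    _contract_invalid_losses(out)
    return out


def valid_moves(tree: PhyloTree) -> list[tuple[int, int]]:
    """All legal (u, v) SPR pairs, in deterministic order."""
    moves = []
    for u in tree.nodes():
        if u == tree.root:
            continue
        inside = set(tree.subtree_nodes(u))
        par = tree.parent(u)
        for v in tree.nodes():
            if v in inside or v == par:
                continue
            moves.append((u, v))
    return moves


def sample_neighbor(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """A uniformly random SPR neighbor; the tree itself when no move exists."""
    moves = valid_moves(tree)
    if not moves:
        return tree
    u, v = moves[int(rng.integers(len(moves)))]
    return spr_move(tree, u, v)


def hill_climb(
    start: PhyloTree,
    I: SCSMatrix,
    rates: ErrorRates,
    config: HillClimbConfig,
) -> tuple[PhyloTree, CellAttachment, float]:
    """Randomized hill climbing from ``start``; returns the best tree seen.

    Each iteration draws ``neighbor_samples`` random neighbors, scores each
    by optimal cell attachment, and moves to the best neighbor only on
    strict improvement (plateaus do not move).  The returned likelihood is
    always >= the score of ``start``.
    """
    rng = np.random.default_rng(config.seed)
    current = start
    cur_att, cur_score = best_attachment(current, I, rates)
    best = (current, cur_att, cur_score)
    for _ in range(config.max_iterations):
        cand_best: tuple[PhyloTree, CellAttachment, float] | None = None
        for _ in range(config.neighbor_samples):
            neigh = sample_neighbor(current, rng)
            att, score = best_attachment(neigh, I, rates)
            if cand_best is None or score > cand_best[2]:
                cand_best = (neigh, att, score)
        if cand_best is not None and cand_best[2] > cur_score:
            current, cur_att, cur_score = cand_best
            if cur_score > best[2]:
                best = (current, cur_att, cur_score)
    return best
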