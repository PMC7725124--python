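"""Clonal-tree simulator with sequencing-noise injection.

The generator emulates a tumor sequenced at single-cell resolution: a random
clonal tree of ``n_subclones`` nodes is grown by repeatedly attaching a new
subclone under a uniformly chosen existing one; each mutation is assigned to
a uniformly random subclone (so one subclone node may carry several gains,
or none); then ``n_deletions`` deletion nodes are added, each hung under a
uniformly chosen node whose genotype still offers an eligible mutation,
deleting a uniformly chosen mutation that is present in the parent's
genotype and has not been deleted before — deleted mutations are pairwise
distinct, so the ground truth is Dollo(1).  Cells are assigned independently
and uniformly with repetition over all tree nodes (germline, subclone and
deletion nodes alike) and their true genotypes are read off the tree.
Observation noise flips 1->0 with probability ``alpha`` (false negatives)
and 0->1 with probability ``beta`` (false positives); independently, each
entry is masked as missing with probability ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extended import Gain, Loss
from .matrix import MISSING, SCSMatrix
from .tree import CellAttachment, PhyloTree, genotype_matrix, is_dollo_k


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults reproduce the reference simulation setting: 9 subclones, 100
    cells by 30 mutations, at most 5 deletions, false-negative rate 0.1,
    false-positive rate 1e-4 and missing-entry rate 0.1 (rates typical of
    current whole-genome-amplified single-cell DNA sequencing).
    """

    n_subclones: int = 9
    n_cells: int = 100
    n_mutations: int = 30
    n_deletions: int = 5
    alpha: float = 0.1
    beta: float = 1e-4
    gamma: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subclones < 1:
            raise ValueError("need at least one subclone")
        if self.n_deletions > self.n_mutations:
            raise ValueError("cannot delete more mutations than exist")
        for name in ("alpha", "beta", "gamma"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SimulationBundle:
    truth_tree: PhyloTree
    truth_attachment: CellAttachment
    truth_matrix: np.ndarray
    observed: SCSMatrix
    config: SimulationConfig


def generate_clonal_tree(config: SimulationConfig, rng: np.random.Generator) -> PhyloTree:
    """Random clonal tree with mutation gains and distinct-mutation deletions.

    The germline root sits above the founding clone; each subclone is one
    node carrying the gains assigned to it (possibly none); each deletion is
    a one-loss node.
    """
    S, M = config.n_subclones, config.n_mutations
    # clonal-tree parents: subclone 0 is the founding clone under the germline
    parents = [-1] + [int(rng.integers(i)) for i in range(1, S)]
    assignment = rng.integers(S, size=M)  # mutation -> subclone
    tree = PhyloTree()
    clone_node: list[int] = []
    for s in range(S):
        base = tree.root if parents[s] == -1 else clone_node[parents[s]]
        gains = [Gain(int(mut)) for mut in np.flatnonzero(assignment == s)]
        clone_node.append(tree.add_node(gains, base))

    deleted: set[int] = set()
    for _ in range(config.n_deletions):
        candidates = [
            node
            for node in tree.nodes()
            if node != tree.root and (tree.node_state(node) - deleted)
        ]
        if not candidates:
            raise SimulationError(
                "no node offers an undeleted mutation; reduce n_deletions"
            )
        parent = candidates[int(rng.integers(len(candidates)))]
        choices = sorted(tree.node_state(parent) - deleted)
        mut = choices[int(rng.integers(len(choices)))]
        tree.add_node(Loss(int(mut), 1), parent)
        deleted.add(mut)
    assert is_dollo_k(tree, 1)
    return tree


def sample_cells(
    tree: PhyloTree,
    n_cells: int,
    rng: np.random.Generator,
    n_mutations: int | None = None,
) -> tuple[CellAttachment, np.ndarray]:
    """Attach cells independently and uniformly (with repetition) to tree nodes."""
    pool = tree.nodes()
    picks = [pool[int(i)] for i in rng.integers(len(pool), size=n_cells)]
    attachment = CellAttachment(picks)
    if n_mutations is None:
        n_mutations = (max(tree.mutations()) + 1) if tree.mutations() else 0
    return attachment, genotype_matrix(tree, attachment, n_mutations)


def add_noise(
    truth: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
    rng: np.random.Generator,
) -> SCSMatrix:
    """Flip entries by the error channel, then mask each as missing w.p. gamma."""
    truth = np.asarray(truth, dtype=np.int8)
    flip = np.where(
        truth == 1, rng.random(truth.shape) < alpha, rng.random(truth.shape) < beta
    )
    observed = np.where(flip, 1 - truth, truth).astype(np.int8)
    observed[rng.random(truth.shape) < gamma] = MISSING
    return SCSMatrix(observed)


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Full pipeline: clonal tree -> cell genotypes -> noisy observations."""
    rng = np.random.default_rng(config.seed)
    tree = generate_clonal_tree(config, rng)
    attachment, truth = sample_cells(
        tree, config.n_cells, rng, n_mutations=config.n_mutations
    )
    observed = add_noise(truth, config.alpha, config.beta, config.gamma, rng)
    return SimulationBundle(
        truth_tree=tree,
        truth_attachment=attachment,
        truth_matrix=truth,
        observed=observed,
        config=config,
    )
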