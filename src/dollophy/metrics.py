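"""Ancestor-Descendant and Different-Lineage accuracy between two phylogenies.

Both measures look only at where mutations are *gained*: an ordered pair
(x, y) is Ancestor-Descendant (AD) when the gain of x is a proper ancestor
of the gain of y; an unordered pair is Different-Lineage (DL) when neither
gain is an ancestor of the other.  Each measure is the F1 score (harmonic
mean of precision and recall) of the ground-truth relation set against the
inferred one.  Loss nodes never enter the classification, so a method that
infers the wrong loss placements is neither rewarded nor penalized here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tree import PhyloTree


@dataclass
class PairClassification:
    ad_pairs: set[tuple[int, int]]  # ordered: x strictly ancestral to y
    dl_pairs: set[frozenset[int]]  # unordered, different branches
    same_node_pairs: set[frozenset[int]]  # gained at the very same node


def classify_pairs(tree: PhyloTree) -> PairClassification:
    """Classify every mutation pair by the relation of their gain nodes."""
    muts = tree.mutations()
    gains = {}
    for m in muts:
        node = tree.gain_node(m)
        if node is None:
            raise ValueError(f"mutation {m} has no gain node")
        gains[m] = node
    ancestors = {m: set(tree.path_from_root(gains[m])[:-1]) for m in muts}
    ad: set[tuple[int, int]] = set()
    dl: set[frozenset[int]] = set()
    same: set[frozenset[int]] = set()
    for i, x in enumerate(muts):
        for y in muts[i + 1 :]:
            if gains[x] == gains[y]:
                same.add(frozenset((x, y)))
            elif gains[x] in ancestors[y]:
                ad.add((x, y))
            elif gains[y] in ancestors[x]:
                ad.add((y, x))
            else:
                dl.add(frozenset((x, y)))
    return PairClassification(ad_pairs=ad, dl_pairs=dl, same_node_pairs=same)


def _f_measure(truth_set: set, inferred_set: set) -> float:
    hits = len(truth_set & inferred_set)
    if not inferred_set and not truth_set:
        return 1.0
    precision = hits / len(inferred_set) if inferred_set else (1.0 if not truth_set else 0.0)
    recall = hits / len(truth_set) if truth_set else (1.0 if not inferred_set else 0.0)
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _check_same_mutations(truth: PhyloTree, inferred: PhyloTree) -> None:
    extra = set(inferred.mutations()) - set(truth.mutations())
    if extra:
        raise ValueError(
            f"inferred tree contains mutations absent from the truth: {sorted(extra)}"
        )


def ad_f_measure(truth: PhyloTree, inferred: PhyloTree) -> float:
    """F1 of preserved strict ancestor-descendant (ordered) mutation pairs.

    Pairs gained at the same node, in either tree, are excluded from both
    relation sets.  A mutation missing from the inferred tree (a tool may
    call it absent everywhere) keeps its truth pairs in the recall
    denominator, where they count as unpreserved.
    """
    _check_same_mutations(truth, inferred)
    t = classify_pairs(truth)
    i = classify_pairs(inferred)
    excluded = t.same_node_pairs | i.same_node_pairs
    t_ad = {p for p in t.ad_pairs if frozenset(p) not in excluded}
    i_ad = {p for p in i.ad_pairs if frozenset(p) not in excluded}
    return _f_measure(t_ad, i_ad)


def dl_f_measure(truth: PhyloTree, inferred: PhyloTree) -> float:
    """F1 of preserved different-lineage (unordered) mutation pairs."""
    _check_same_mutations(truth, inferred)
    t = classify_pairs(truth)
    i = classify_pairs(inferred)
    excluded = t.same_node_pairs | i.same_node_pairs
    return _f_measure(t.dl_pairs - excluded, i.dl_pairs - excluded)
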