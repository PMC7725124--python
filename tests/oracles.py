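"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (direct table
lookups, exhaustive enumeration) and never calls the code paths it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

MISSING = 2


def entry_ll_table(observed: int, predicted: int, alpha: float, beta: float) -> float:
    """Direct conditional-table lookup, the slow reference for the error model."""
    if observed == MISSING:
        return 0.0
    table = {
        (1, 1): 1.0 - alpha,
        (0, 1): alpha,
        (1, 0): beta,
        (0, 0): 1.0 - beta,
    }
    return float(np.log(table[(observed, predicted)]))


def brute_matrix_ll(I: np.ndarray, F: np.ndarray, alpha: float, beta: float) -> float:
    total = 0.0
    for c in range(I.shape[0]):
        for m in range(I.shape[1]):
            total += entry_ll_table(int(I[c, m]), int(F[c, m]), alpha, beta)
    return total


def brute_conflict(cols: np.ndarray) -> bool:
    """All-pairs, all-row-pairs scan for the forbidden three configurations."""
    n, K = cols.shape
    for p in range(K):
        for q in range(p + 1, K):
            seen = set()
            for r in range(n):
                seen.add((int(cols[r, p]), int(cols[r, q])))
            if {(0, 1), (1, 0), (1, 1)} <= seen:
                return True
    return False


@lru_cache(maxsize=None)
def dollo1_state_collections(n_mut: int) -> tuple:
    """Reachable-state collections of every Dollo(1) tree on ``n_mut`` mutations.

    Enumerates all rooted trees whose nodes are the root, one gain per
    mutation and any subset of single losses (each loss strictly below its
    gain), collects each tree's set of node states, and keeps the maximal
    collections under inclusion — sufficient for optima because a tree with
    more reachable states can only score better.
    """
    collections: set[frozenset] = set()
    muts = list(range(n_mut))
    for loss_subset in itertools.chain.from_iterable(
        itertools.combinations(muts, r) for r in range(n_mut + 1)
    ):
        labels = [("+", m) for m in muts] + [("-", m) for m in loss_subset]
        t = len(labels)
        # parent of node i (1-based over labels) among {0 (root)} + other labels
        for parents in itertools.product(range(t + 1), repeat=t):
            ok = True
            for i, p in enumerate(parents, start=1):
                if p == i:
                    ok = False
                    break
            if not ok:
                continue
            # acyclicity: every node reaches the root
            for i in range(1, t + 1):
                seen = set()
                cur = i
                while cur != 0:
                    if cur in seen:
                        ok = False
                        break
                    seen.add(cur)
                    cur = parents[cur - 1]
                if not ok:
                    break
            if not ok:
                continue
            # each loss strictly below its gain
            for i in range(1, t + 1):
                kind, m = labels[i - 1]
                if kind != "-":
                    continue
                cur = parents[i - 1]
                while cur != 0 and labels[cur - 1] != ("+", m):
                    cur = parents[cur - 1]
                if cur == 0:
                    ok = False
                    break
            if not ok:
                continue
            states = set()
            for i in range(t + 1):
                path = []
                cur = i
                while cur != 0:
                    path.append(labels[cur - 1])
                    cur = parents[cur - 1]
                st = set()
                for kind, m in reversed(path):
                    if kind == "+":
                        st.add(m)
                    else:
                        st.discard(m)
                states.add(frozenset(st))
            collections.add(frozenset(states))
    maximal = [
        s for s in collections if not any(s < other for other in collections)
    ]
    out = []
    for coll in maximal:
        S = np.zeros((len(coll), n_mut), dtype=np.int8)
        for i, st in enumerate(sorted(coll, key=sorted)):
            for m in st:
                S[i, m] = 1
        out.append(S)
    return tuple(out)


def brute_force_dollo1_optimum(I: np.ndarray, alpha: float, beta: float) -> float:
    """Exhaustive maximum log-likelihood over all Dollo(1) trees + attachments."""
    n_mut = I.shape[1]
    best = -np.inf
    for S in dollo1_state_collections(n_mut):
        total = 0.0
        for c in range(I.shape[0]):
            cell_best = max(
                sum(
                    entry_ll_table(int(I[c, m]), int(S[x, m]), alpha, beta)
                    for m in range(n_mut)
                )
                for x in range(S.shape[0])
            )
            total += cell_best
        best = max(best, total)
    return best


def pair_relations(tree) -> tuple[set, set, set]:
    """(AD ordered, DL unordered, same-node unordered) pairs via raw path walks."""
    muts = tree.mutations()
    gain_of = {}
    for n in tree.nodes():
        for lab in tree.labels(n):
            if type(lab).__name__ == "Gain":
                gain_of[lab.mutation] = n

    def is_proper_ancestor(a: int, b: int) -> bool:
        cur = tree.parent(b)
        while cur is not None:
            if cur == a:
                return True
            cur = tree.parent(cur)
        return False

    ad, dl, same = set(), set(), set()
    for x in muts:
        for y in muts:
            if x >= y:
                continue
            gx, gy = gain_of[x], gain_of[y]
            if gx == gy:
                same.add(frozenset((x, y)))
            elif is_proper_ancestor(gx, gy):
                ad.add((x, y))
            elif is_proper_ancestor(gy, gx):
                ad.add((y, x))
            else:
                dl.add(frozenset((x, y)))
    return ad, dl, same


def brute_f1(truth_set: set, inferred_set: set) -> float:
    hits = len(truth_set & inferred_set)
    if not truth_set and not inferred_set:
        return 1.0
    p = hits / len(inferred_set) if inferred_set else (1.0 if not truth_set else 0.0)
    r = hits / len(truth_set) if truth_set else (1.0 if not inferred_set else 0.0)
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)
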