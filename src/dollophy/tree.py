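"""Rooted mutation-gain/loss phylogenies.

A tumor phylogeny here is a rooted tree whose root is the unlabeled
germline; every other node carries a tuple of labels — mutation gains
``m+`` and/or losses ``m_l-`` that happen on the edge above it (several
events on one edge share one node; a subclone that acquired no private
mutation is a node with an empty label tuple).  The *state* of a node is
the set of mutations acquired and not subsequently lost on the root path;
a cell attached at a node is predicted to carry exactly that state.

Trees are extracted from conflict-free completed extended matrices with the
classic directed perfect-phylogeny construction (identical columns merge
onto one node), and cells are (re)attached by maximizing their individual
observation likelihood, which is globally optimal because cells are
independent given the tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .error_model import ErrorRates, objective_coefficients
from .extended import Column, ExtendedMatrix, Gain, Loss, is_conflict_free
from .matrix import SCSMatrix


def _as_labels(labels: Column | Iterable[Column] | None) -> tuple[Column, ...]:
    if labels is None:
        return ()
    if isinstance(labels, (Gain, Loss)):
        return (labels,)
    return tuple(labels)


class PhyloTree:
    """Rooted tree with an unlabeled root and label-tuple nodes.

    Node ids are small ints assigned in creation order; the root is id 0.
    Child lists preserve insertion order, so traversals are deterministic.
    """

    def __init__(self) -> None:
        self._labels: dict[int, tuple[Column, ...]] = {0: ()}
        self._parent: dict[int, int | None] = {0: None}
        self._children: dict[int, list[int]] = {0: []}
        self._next_id = 1

    # -- construction ------------------------------------------------------

    @property
    def root(self) -> int:
        return 0

    def add_node(self, labels: Column | Iterable[Column] | None, parent: int) -> int:
        if parent not in self._labels:
            raise KeyError(f"unknown parent node {parent}")
        nid = self._next_id
        self._next_id += 1
        self._labels[nid] = _as_labels(labels)
        self._parent[nid] = parent
        self._children[nid] = []
        self._children[parent].append(nid)
        return nid

    def copy(self) -> "PhyloTree":
        t = PhyloTree.__new__(PhyloTree)
        t._labels = dict(self._labels)
        t._parent = dict(self._parent)
        t._children = {k: list(v) for k, v in self._children.items()}
        t._next_id = self._next_id
        return t

    # -- queries -----------------------------------------------------------

    def nodes(self) -> list[int]:
        return sorted(self._labels)

    def __contains__(self, node: int) -> bool:
        return node in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def labels(self, node: int) -> tuple[Column, ...]:
        return self._labels[node]

    def set_labels(self, node: int, labels: Iterable[Column]) -> None:
        self._labels[node] = tuple(labels)

    def parent(self, node: int) -> int | None:
        return self._parent[node]

    def children(self, node: int) -> list[int]:
        return list(self._children[node])

    def path_from_root(self, node: int) -> list[int]:
        if node not in self._labels:
            raise KeyError(f"unknown node {node}")
        path = []
        cur: int | None = node
        while cur is not None:
            path.append(cur)
            cur = self._parent[cur]
        return path[::-1]

    def subtree_nodes(self, node: int) -> list[int]:
        """Preorder node ids of the subtree rooted at ``node``."""
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(self._children[cur]))
        return out

    def loss_labels(self) -> list[tuple[int, Loss]]:
        """All (node, Loss) occurrences, in node-id order."""
        out = []
        for n in self.nodes():
            out.extend((n, lab) for lab in self._labels[n] if isinstance(lab, Loss))
        return out

    def loss_nodes(self) -> list[int]:
        """Nodes carrying at least one loss label."""
        return sorted({n for n, _ in self.loss_labels()})

    def n_losses(self) -> int:
        return len(self.loss_labels())

    def gain_node(self, mutation: int) -> int | None:
        for n in self.nodes():
            for lab in self._labels[n]:
                if isinstance(lab, Gain) and lab.mutation == mutation:
                    return n
        return None

    def mutations(self) -> list[int]:
        return sorted(
            {
                lab.mutation
                for labs in self._labels.values()
                for lab in labs
                if isinstance(lab, Gain)
            }
        )

    # -- structural edits (used by the SPR neighborhood) --------------------

    def detach(self, node: int) -> None:
        """Remove the edge above ``node``; the subtree keeps its ids."""
        if node == self.root:
            raise ValueError("cannot detach the root")
        par = self._parent[node]
        self._children[par].remove(node)
        self._parent[node] = None

    def attach(self, node: int, parent: int) -> None:
        if self._parent[node] is not None:
            raise ValueError(f"node {node} is already attached")
        self._parent[node] = parent
        self._children[parent].append(node)

    def contract(self, node: int) -> None:
        """Remove ``node``, reattaching its children to its parent in place."""
        if node == self.root:
            raise ValueError("cannot contract the root")
        par = self._parent[node]
        pos = self._children[par].index(node)
        kids = self._children[node]
        self._children[par][pos : pos + 1] = kids
        for kid in kids:
            self._parent[kid] = par
        del self._labels[node], self._parent[node], self._children[node]

    # -- states ------------------------------------------------------------

    @staticmethod
    def _apply_labels(state: frozenset[int], labels: tuple[Column, ...]) -> frozenset[int]:
        st = set(state)
        for lab in labels:  # gains before losses: a gain+loss pair cancels
            if isinstance(lab, Gain):
                st.add(lab.mutation)
        for lab in labels:
            if isinstance(lab, Loss):
                st.discard(lab.mutation)
        return frozenset(st)

    def node_state(self, node: int) -> frozenset[int]:
        """Mutations acquired and not lost on the root -> node path."""
        state: frozenset[int] = frozenset()
        for n in self.path_from_root(node):
            state = self._apply_labels(state, self._labels[n])
        return state

    def states_matrix(self, n_mutations: int) -> tuple[list[int], np.ndarray]:
        """All node states as a (n_nodes, n_mutations) binary array.

        Computed in one preorder sweep; nodes are returned sorted by id so
        argmax ties resolve to the smallest node id.
        """
        states: dict[int, frozenset[int]] = {}
        stack: list[tuple[int, frozenset[int]]] = [(self.root, frozenset())]
        while stack:
            node, st = stack.pop()
            st = self._apply_labels(st, self._labels[node])
            states[node] = st
            for kid in self._children[node]:
                stack.append((kid, st))
        ids = self.nodes()
        S = np.zeros((len(ids), n_mutations), dtype=np.int8)
        for i, n in enumerate(ids):
            for m in states[n]:
                S[i, m] = 1
        return ids, S


@dataclass
class CellAttachment:
    """Total mapping from each cell index to a node id of a tree."""

    nodes: list[int]

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, cell: int) -> int:
        return self.nodes[cell]


def is_dollo_k(tree: PhyloTree, k: int) -> bool:
    """Each mutation gained at most once, lost at most ``k`` times, and every
    loss fires on a mutation that is actually active at that point of the
    root path (so it sits below its gain with no earlier loss in between)."""
    gain_count: dict[int, int] = {}
    loss_count: dict[int, int] = {}
    for n in tree.nodes():
        for lab in tree.labels(n):
            if isinstance(lab, Gain):
                gain_count[lab.mutation] = gain_count.get(lab.mutation, 0) + 1
            else:
                loss_count[lab.mutation] = loss_count.get(lab.mutation, 0) + 1
    if any(c > 1 for c in gain_count.values()):
        return False
    if any(c > k for c in loss_count.values()):
        return False
    # every loss must apply to an active mutation, walking states root-down
    ok = True
    stack: list[tuple[int, frozenset[int]]] = [(tree.root, frozenset())]
    while stack and ok:
        node, state = stack.pop()
        st = set(state)
        for lab in tree.labels(node):
            if isinstance(lab, Gain):
                st.add(lab.mutation)
        for lab in tree.labels(node):
            if isinstance(lab, Loss):
                if lab.mutation not in st:
                    ok = False
                st.discard(lab.mutation)
        for kid in tree.children(node):
            stack.append((kid, frozenset(st)))
    return ok


def tree_from_extended_matrix(
    E: ExtendedMatrix, return_row_nodes: bool = False
) -> PhyloTree | tuple[PhyloTree, list[int]]:
    """Directed perfect-phylogeny construction on a conflict-free matrix.

    Columns are processed by decreasing number of 1s (ties by column index);
    all-zero columns are omitted; identical columns merge onto a single node
    carrying all their labels (the representative is the lowest index).
    Each row maps to the node reached after its last 1-column; with
    ``return_row_nodes`` that mapping is returned too.
    """
    if not is_conflict_free(E):
        raise ValueError("extended matrix has conflicting columns")
    entries = E.entries
    counts = entries.sum(axis=0)
    nonzero = [j for j in range(entries.shape[1]) if counts[j] > 0]
    # group identical columns; groups keyed by their representative column
    groups: dict[bytes, list[int]] = {}
    for j in nonzero:
        groups.setdefault(entries[:, j].tobytes(), []).append(j)
    reps = sorted(groups.values(), key=lambda g: (-int(counts[g[0]]), g[0]))
    tree = PhyloTree()
    group_node: dict[int, int] = {}  # representative column -> node id
    row_nodes: list[int] = []
    for r in range(entries.shape[0]):
        cur = tree.root
        for grp in reps:
            if not entries[r, grp[0]]:
                continue
            if grp[0] in group_node:
                # conflict-freeness guarantees the edge hangs where we stand
                cur = group_node[grp[0]]
            else:
                cur = tree.add_node([E.columns[j] for j in grp], cur)
                group_node[grp[0]] = cur
        row_nodes.append(cur)
    if return_row_nodes:
        return tree, row_nodes
    return tree


def genotype_matrix(
    tree: PhyloTree, attachment: CellAttachment, n_mutations: int
) -> np.ndarray:
    """Complete binary matrix whose row c is the state of node sigma(c)."""
    ids, S = tree.states_matrix(n_mutations)
    index = {n: i for i, n in enumerate(ids)}
    rows = [S[index[attachment[c]]] for c in range(len(attachment))]
    if not rows:
        return np.zeros((0, n_mutations), dtype=np.int8)
    return np.stack(rows).astype(np.int8)


def best_attachment(
    tree: PhyloTree, I: SCSMatrix, rates: ErrorRates
) -> tuple[CellAttachment, float]:
    """Attach each cell to its likelihood-maximizing node (ties: smallest id).

    Per-cell optimality implies global optimality since cells are independent
    given the tree; the returned score is the total log-likelihood.
    """
    ids, S = tree.states_matrix(I.n_mutations)
    slope, intercept = objective_coefficients(I, rates)
    # score[c, x] = sum_m slope[c,m] * S[x,m] + sum_m intercept[c,m]
    scores = slope @ S.T + intercept.sum(axis=1, keepdims=True)
    choice = np.argmax(scores, axis=1)
    # recompute the total with the same arithmetic as matrix_log_likelihood so
    # identical genotype matrices yield bit-identical scores across code paths
    total = float(np.sum(slope * S[choice]) + np.sum(intercept))
    return CellAttachment([ids[i] for i in choice]), total


def extended_matrix_from_tree(
    tree: PhyloTree, attachment: CellAttachment, n_mutations: int, k: int
) -> ExtendedMatrix:
    """The completed extended matrix a tree + attachment induces.

    Row c marks every gain/loss label occurring on the root path of the
    cell's node.  Tree-path indicators are laminar, so the result is always
    conflict-free, and on any root path a mutation is gained once and lost
    at most once, so the gain-minus-losses differences stay in {0, 1}.
    """
    from .extended import extended_columns  # local: avoids import clutter

    columns = extended_columns(n_mutations, k)
    col_index = {col: i for i, col in enumerate(columns)}
    # per-node indicator of labels seen on the root path, one preorder sweep
    indicators: dict[int, frozenset[Column]] = {}
    stack: list[tuple[int, frozenset[Column]]] = [(tree.root, frozenset())]
    while stack:
        node, seen = stack.pop()
        seen = seen | frozenset(tree.labels(node))
        indicators[node] = seen
        for kid in tree.children(node):
            stack.append((kid, seen))
    entries = np.zeros((len(attachment), len(columns)), dtype=np.int8)
    for c in range(len(attachment)):
        for lab in indicators[attachment[c]]:
            entries[c, col_index[lab]] = 1
    return ExtendedMatrix(columns=columns, entries=entries)


# -- DOT export / import ---------------------------------------------------


def _label_display(label: Column, mutation_labels: list[str] | None) -> str:
    name = (
        mutation_labels[label.mutation]
        if mutation_labels
        else f"mut{label.mutation + 1}"
    )
    if isinstance(label, Gain):
        return name
    return f"{name}-" if label.copy == 1 else f"{name}-{label.copy}"


def _node_display(labels: tuple[Column, ...], mutation_labels: list[str] | None) -> str:
    if not labels:
        return "·"
    return ", ".join(_label_display(lab, mutation_labels) for lab in labels)


def to_dot(
    tree: PhyloTree,
    attachment: CellAttachment | None = None,
    collapse_linear_paths: bool = False,
    mutation_labels: list[str] | None = None,
    cell_labels: list[str] | None = None,
) -> str:
    """Render the tree as a DOT digraph; nodes carrying a loss are drawn red.

    ``collapse_linear_paths`` merges chains of only-child loss-free display
    nodes into a single multi-label node, for figures only — the underlying
    tree is unchanged.
    """
    display: dict[int, str] = {}
    loss_flag: dict[int, bool] = {}
    parent_of: dict[int, int] = {}
    for n in tree.nodes():
        display[n] = _node_display(tree.labels(n), mutation_labels)
        loss_flag[n] = any(isinstance(lab, Loss) for lab in tree.labels(n))
        if tree.parent(n) is not None:
            parent_of[n] = tree.parent(n)
    kept = set(tree.nodes())
    if collapse_linear_paths:
        for n in sorted(tree.nodes()):
            if n == tree.root:
                continue
            par = parent_of[n]
            while par not in kept:
                par = parent_of[par]
            if (
                len(tree.children(tree.parent(n))) == 1
                and par != tree.root
                and not loss_flag[n]
                and not loss_flag[par]
            ):
                display[par] = display[par] + ", " + display[n]
                kept.discard(n)
    cells_at: dict[int, list[str]] = {}
    if attachment is not None:
        for c, node in enumerate(attachment.nodes):
            target = node
            while target not in kept:
                target = parent_of[target]
            name = cell_labels[c] if cell_labels else f"cell{c + 1}"
            cells_at.setdefault(target, []).append(name)
    lines = ["digraph phylogeny {", "  node [shape=box];"]
    root_label = "germline"
    for n in sorted(kept):
        label = root_label if n == tree.root else display[n]
        if n in cells_at:
            label += "\\n[" + ",".join(cells_at[n]) + "]"
        style = ' style=filled fillcolor="indianred1"' if loss_flag.get(n) else ""
        lines.append(f'  n{n} [label="{label}"{style}];')
    for n in sorted(kept):
        if n == tree.root:
            continue
        par = parent_of[n]
        while par not in kept:
            par = parent_of[par]
        lines.append(f"  n{par} -> n{n};")
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_NODE = re.compile(r'^\s*n(\d+)\s*\[label="([^"\\]*)"')
_DOT_EDGE = re.compile(r"^\s*n(\d+)\s*->\s*n(\d+)")


def read_dot(path) -> tuple[PhyloTree, list[str]]:
    """Parse an (uncollapsed, attachment-free) DOT tree written by this package.

    Returns the tree and the mutation-name list backing its label indices
    (names sorted alphabetically).  Loss labels are recognized by a trailing
    ``-`` or ``-<copy>`` suffix on a known gain name; ``·`` is an unlabeled
    node.
    """
    raw_label: dict[int, str] = {}
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            mn = _DOT_NODE.match(line)
            if mn:
                raw_label[int(mn.group(1))] = mn.group(2)
                continue
            me = _DOT_EDGE.match(line)
            if me:
                edges.append((int(me.group(1)), int(me.group(2))))
    parent = {c: p for p, c in edges}
    roots = [n for n in raw_label if n not in parent]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root in {path}, found {len(roots)}")

    def tokens(node: int) -> list[str]:
        lab = raw_label[node]
        if node == roots[0] or lab in ("germline", "·", ""):
            return []
        return [t.strip() for t in lab.split(",") if t.strip() and t.strip() != "·"]

    gain_names = sorted(
        {
            t
            for n in raw_label
            for t in tokens(n)
            if not re.search(r"-\d*$", t)
        }
    )
    name_index = {name: i for i, name in enumerate(gain_names)}

    def parse_label(t: str) -> Column:
        if t in name_index:
            return Gain(name_index[t])
        m = re.match(r"^(.*?)-(\d*)$", t)
        if m and m.group(1) in name_index:
            copy = int(m.group(2)) if m.group(2) else 1
            return Loss(name_index[m.group(1)], copy)
        raise ValueError(f"cannot interpret node label {t!r}")

    children: dict[int, list[int]] = {n: [] for n in raw_label}
    for p, c in edges:
        children[p].append(c)
    tree = PhyloTree()
    id_map = {roots[0]: tree.root}
    stack = [roots[0]]
    while stack:
        cur = stack.pop(0)
        for kid in sorted(children[cur]):
            id_map[kid] = tree.add_node(
                [parse_label(t) for t in tokens(kid)], id_map[cur]
            )
            stack.append(kid)
    return tree, gain_names
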