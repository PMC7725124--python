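"""The gain/loss extended column space and perfect-phylogeny conflict tests.

Under Dollo(k), each mutation ``m`` is acquired exactly once and may be lost
at most ``k`` times.  The reduction at the heart of the method replaces the
single column of ``m`` by one *gain* column ``m+`` and ``k`` *loss* columns
``m_1-`` ... ``m_k-``: an incomplete matrix has a Dollo(k) completion iff the
extended matrix has a conflict-free (directed perfect phylogeny) binary
completion whose gain-minus-losses differences reproduce the original
entries.  Two binary columns *conflict* when some rows exhibit all three of
the configurations (0,1), (1,0) and (1,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import SCSMatrix


@dataclass(frozen=True, order=True)
class Gain:
    """Gain column m+ of a mutation (0-based mutation index)."""

    mutation: int

    def __str__(self) -> str:
        return f"{self.mutation}+"


@dataclass(frozen=True, order=True)
class Loss:
    """Loss column m_l- of a mutation; copies are numbered 1..k."""

    mutation: int
    copy: int

    def __str__(self) -> str:
        return f"{self.mutation}-{self.copy}"


Column = Gain | Loss


def extended_columns(n_mutations: int, k: int) -> list[Column]:
    """Ordered column identities: Gain(j), Loss(j,1)..Loss(j,k) per mutation."""
    if k < 0:
        raise ValueError("k must be >= 0")
    cols: list[Column] = []
    for j in range(n_mutations):
        cols.append(Gain(j))
        cols.extend(Loss(j, l) for l in range(1, k + 1))
    return cols


@dataclass
class ExtendedMatrix:
    """A complete binary matrix over the extended gain/loss column space."""

    columns: list[Column]
    entries: np.ndarray  # (n_cells, len(columns)) binary

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2 or self.entries.shape[1] != len(self.columns):
            raise ValueError("entries shape does not match the column list")
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("extended matrix entries must be binary")

    @property
    def n_cells(self) -> int:
        return self.entries.shape[0]

    @property
    def n_mutations(self) -> int:
        return sum(1 for c in self.columns if isinstance(c, Gain))

    @property
    def k(self) -> int:
        losses = [c for c in self.columns if isinstance(c, Loss)]
        g = self.n_mutations
        return len(losses) // g if g else 0

    def column_vector(self, col: Column) -> np.ndarray:
        return self.entries[:, self.columns.index(col)]

    def dollo_differences(self) -> np.ndarray:
        """Per-mutation gain minus sum-of-losses; the implied complete matrix."""
        gains = [i for i, c in enumerate(self.columns) if isinstance(c, Gain)]
        out = np.zeros((self.n_cells, len(gains)), dtype=np.int64)
        for j, gi in enumerate(gains):
            mut = self.columns[gi].mutation
            loss_idx = [
                i
                for i, c in enumerate(self.columns)
                if isinstance(c, Loss) and c.mutation == mut
            ]
            out[:, j] = self.entries[:, gi].astype(np.int64) - self.entries[
                :, loss_idx
            ].sum(axis=1)
        return out


def columns_in_conflict(col_p: np.ndarray, col_q: np.ndarray) -> bool:
    """True iff rows exhibiting (0,1), (1,0) and (1,1) all exist."""
    p = np.asarray(col_p, dtype=bool)
    q = np.asarray(col_q, dtype=bool)
    if p.shape != q.shape:
        raise ValueError("columns must have equal length")
    return bool((~p & q).any() and (p & ~q).any() and (p & q).any())


def is_conflict_free(E: ExtendedMatrix | np.ndarray) -> bool:
    """True iff no unordered pair of distinct columns is in conflict."""
    entries = E.entries if isinstance(E, ExtendedMatrix) else np.asarray(E)
    ncol = entries.shape[1]
    b = entries.astype(bool)
    for p in range(ncol):
        for q in range(p + 1, ncol):
            if (
                (~b[:, p] & b[:, q]).any()
                and (b[:, p] & ~b[:, q]).any()
                and (b[:, p] & b[:, q]).any()
            ):
                return False
    return True


def check_dollo_completion(E: ExtendedMatrix, I: SCSMatrix, F: np.ndarray) -> bool:
    """Check the completion consistency conditions linking E, I and F.

    For every cell c and mutation m the difference
    ``E(c, m+) - sum_l E(c, m_l-)`` must lie in {0, 1} and equal ``F(c, m)``.
    ``I`` fixes the expected shape (F is its complete binary counterpart).
    """
    F = np.asarray(F)
    if F.shape != (I.n_cells, I.n_mutations):
        raise ValueError("F shape does not match I")
    if E.n_cells != I.n_cells or E.n_mutations != I.n_mutations:
        raise ValueError("E shape does not match I")
    diff = E.dollo_differences()
    if not np.isin(diff, (0, 1)).all():
        return False
    return bool(np.array_equal(diff, F))
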