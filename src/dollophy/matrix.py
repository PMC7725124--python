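"""Incomplete single-cell mutation matrices and their on-disk dialect.

The observation matrix ``I`` is a cells x mutations grid over three states:
0 (mutation absent), 1 (mutation present) and MISSING (no call, usually due
to insufficient coverage).  On disk the dialect is the one shared by most
single-cell phylogeny tools: whitespace-separated ``0``/``1``/``2`` tokens,
one row per line, where ``2`` encodes a missing entry.  Row/column labels
live in optional sidecar files, one label per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing (uncalled) entry, both in memory and on disk.
MISSING: int = 2

_VALID_TOKENS = {"0", "1", "2"}


class MatrixFormatError(ValueError):
    """Raised when an input file does not follow the 0/1/2 dialect."""


@dataclass
class SCSMatrix:
    """An incomplete binary single-cell mutation matrix.

    Parameters
    ----------
    entries:
        ``(n_cells, n_mutations)`` integer array over ``{0, 1, MISSING}``.
    cell_labels, mutation_labels:
        Optional row / column names; autogenerated (``cell1``..., ``mut1``...)
        when omitted.
    """

    entries: np.ndarray
    cell_labels: list[str] = field(default_factory=list)
    mutation_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a 2-D grid")
        bad = ~np.isin(self.entries, (0, 1, MISSING))
        if bad.any():
            raise ValueError(
                f"entries must be 0, 1 or {MISSING}; found {self.entries[bad][0]}"
            )
        if not self.cell_labels:
            self.cell_labels = [f"cell{i + 1}" for i in range(self.n_cells)]
        if not self.mutation_labels:
            self.mutation_labels = [f"mut{j + 1}" for j in range(self.n_mutations)]
        if len(self.cell_labels) != self.n_cells:
            raise ValueError("cell_labels length does not match the number of rows")
        if len(self.mutation_labels) != self.n_mutations:
            raise ValueError("mutation_labels length does not match the number of columns")

    @property
    def n_cells(self) -> int:
        return self.entries.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.entries.shape[1]

    @property
    def known_mask(self) -> np.ndarray:
        """Boolean mask of entries that carry an actual 0/1 call."""
        return self.entries != MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SCSMatrix):
            return NotImplemented
        return (
            self.entries.shape == other.entries.shape
            and bool(np.array_equal(self.entries, other.entries))
            and self.cell_labels == other.cell_labels
            and self.mutation_labels == other.mutation_labels
        )


def read_matrix(
    path,
    orientation: str = "cells-as-rows",
    cell_labels_path=None,
    mutation_labels_path=None,
) -> SCSMatrix:
    """Read a ternary 0/1/2 matrix file.

    ``orientation`` must be ``"cells-as-rows"`` or ``"mutations-as-rows"``;
    in the latter case the grid is transposed so the returned matrix is
    always cells x mutations.  The orientation is never guessed from shape.
    """
    if orientation not in ("cells-as-rows", "mutations-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            for tok in tokens:
                if tok not in _VALID_TOKENS:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: invalid token {tok!r} (expected 0, 1 or 2)"
                    )
            rows.append([int(t) for t in tokens])
            if len(rows[-1]) != len(rows[0]):
                raise MatrixFormatError(
                    f"{path}:{lineno}: ragged row of length {len(rows[-1])} "
                    f"(expected {len(rows[0])})"
                )
    if rows:
        grid = np.array(rows, dtype=np.int8)
    else:
        grid = np.zeros((0, 0), dtype=np.int8)
    if orientation == "mutations-as-rows":
        grid = grid.T
    cells = _read_labels(cell_labels_path) if cell_labels_path else []
    muts = _read_labels(mutation_labels_path) if mutation_labels_path else []
    return SCSMatrix(grid, cell_labels=cells, mutation_labels=muts)


def write_matrix(matrix: SCSMatrix, path) -> None:
    """Write ``matrix`` in the 0/1/2 dialect; round-trips through read_matrix."""
    with open(path, "w") as fh:
        for row in matrix.entries:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def _read_labels(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_labels(labels: list[str], path) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(lab + "\n")
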