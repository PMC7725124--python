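"""Maximum-likelihood ILP over the gain/loss extended matrix.

Variables (all binary):

* ``E(c, p)`` — completed extended matrix entry for cell ``c`` and extended
  column ``p`` (a gain ``m+`` or loss copy ``m_l-``);
* ``F(c, m)`` — predicted genotype, linked by
  ``F(c,m) = E(c,m+) - sum_l E(c,m_l-)`` (with ``F`` binary this also forces
  the gain-dominates-losses inequality);
* ``B(p, q, a, b)`` for unordered column pairs and
  ``(a,b) in {(0,1),(1,0),(1,1)}`` — witness variables pushed up by any cell
  exhibiting that configuration; demanding ``B(p,q,0,1)+B(p,q,1,0)+B(p,q,1,1)
  <= 2`` forbids conflicting pairs, so the completed extended matrix admits a
  directed perfect phylogeny, i.e. the genotypes admit a Dollo(k) phylogeny.

The objective maximizes the observation log-likelihood of ``F`` given the
input matrix, which is linear in ``F`` (per-entry slope/intercept from the
error model).  An optional cap on the number of *used* loss columns and an
optional tiny sparsity penalty on ``E`` (a secondary parsimony preference
that never outweighs a genotype flip) complete the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .error_model import ErrorRates, matrix_log_likelihood, objective_coefficients
from .extended import (
    ExtendedMatrix,
    Loss,
    check_dollo_completion,
    extended_columns,
    is_conflict_free,
)
from .matrix import SCSMatrix
from .solvers import NoIncumbentError, RawSolution, get_solver


@dataclass
class IlpModel:
    """A built model: sparse constraint system plus index bookkeeping."""

    I: SCSMatrix
    rates: ErrorRates
    k: int
    columns: list
    c: np.ndarray  # objective, minimization sense
    A: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    constant: float  # sum of per-entry intercepts
    sparsity_weight: float
    max_losses: int | None
    offsets: dict = field(default_factory=dict)

    @property
    def n_E_vars(self) -> int:
        return self.I.n_cells * len(self.columns)

    @property
    def n_F_vars(self) -> int:
        return self.I.n_cells * self.I.n_mutations

    @property
    def n_B_vars(self) -> int:
        K = len(self.columns)
        return 3 * (K * (K - 1)) // 2

    @property
    def n_variables(self) -> int:
        return int(self.c.shape[0])

    @property
    def n_constraints(self) -> int:
        return int(self.A.shape[0])


@dataclass
class IlpSolution:
    """Solved model: completed extended matrix, genotypes, likelihood, status."""

    status: str  # "optimal" | "feasible-timeout" | "infeasible"
    E_star: ExtendedMatrix | None = None
    F_star: np.ndarray | None = None
    objective: float | None = None


def build_model(
    I: SCSMatrix,
    rates: ErrorRates,
    k: int,
    max_losses: int | None = None,
    sparsity_weight: float = 0.0,
    symmetry_breaking: bool = False,
) -> IlpModel:
    """Assemble the constraint system for the likelihood-maximizing Dollo(k) fit.

    ``symmetry_breaking`` (useful for k >= 2, where loss copies of one
    mutation are interchangeable) allows copy ``l+1`` of a mutation to be
    used only when copy ``l`` is.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n, m = I.n_cells, I.n_mutations
    columns = extended_columns(m, k)
    K = len(columns)
    nE = n * K
    nF = n * m
    pi, qi = np.triu_indices(K, 1)
    P = pi.shape[0]
    oF = nE
    oB = nE + nF
    nB = 3 * P
    loss_cols = np.array(
        [j for j, col in enumerate(columns) if isinstance(col, Loss)], dtype=np.int64
    )
    use_u = max_losses is not None or (symmetry_breaking and k >= 2)
    oU = oB + nB
    nU = loss_cols.shape[0] if use_u else 0
    nvars = oU + nU

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    lbs: list[np.ndarray] = []
    ubs: list[np.ndarray] = []
    row_base = 0

    def add_block(r, cidx, d, lo, hi, nrows):
        nonlocal row_base
        rows.append(r + row_base)
        cols.append(cidx)
        data.append(d)
        lbs.append(np.full(nrows, lo) if np.isscalar(lo) else lo)
        ubs.append(np.full(nrows, hi) if np.isscalar(hi) else hi)
        row_base += nrows

    # linking constraints: F(c,m) - E(c,m+) + sum_l E(c,m_l-) = 0
    cm_c = np.repeat(np.arange(n), m)
    cm_m = np.tile(np.arange(m), n)
    nrows = n * m
    r_ids = np.arange(nrows)
    link_rows = [r_ids, r_ids]
    link_cols = [oF + cm_c * m + cm_m, cm_c * K + cm_m * (k + 1)]
    link_data = [np.ones(nrows), -np.ones(nrows)]
    for l in range(1, k + 1):
        link_rows.append(r_ids)
        link_cols.append(cm_c * K + cm_m * (k + 1) + l)
        link_data.append(np.ones(nrows))
    add_block(
        np.concatenate(link_rows),
        np.concatenate(link_cols),
        np.concatenate(link_data),
        0.0,
        0.0,
        nrows,
    )

    if P:
        # witness constraints, one triple of rows per (cell, column pair)
        c_arr = np.repeat(np.arange(n), P)
        pair_arr = np.tile(np.arange(P), n)
        Ep = c_arr * K + pi[pair_arr]
        Eq = c_arr * K + qi[pair_arr]
        npair_rows = n * P
        r_ids = np.arange(npair_rows)
        # B(p,q,0,1) >= E(c,q) - E(c,p)
        add_block(
            np.concatenate([r_ids, r_ids, r_ids]),
            np.concatenate([oB + 3 * pair_arr, Eq, Ep]),
            np.concatenate([np.ones(npair_rows), -np.ones(npair_rows), np.ones(npair_rows)]),
            0.0,
            np.inf,
            npair_rows,
        )
        # B(p,q,1,0) >= E(c,p) - E(c,q)
        add_block(
            np.concatenate([r_ids, r_ids, r_ids]),
            np.concatenate([oB + 3 * pair_arr + 1, Ep, Eq]),
            np.concatenate([np.ones(npair_rows), -np.ones(npair_rows), np.ones(npair_rows)]),
            0.0,
            np.inf,
            npair_rows,
        )
        # B(p,q,1,1) >= E(c,p) + E(c,q) - 1
        add_block(
            np.concatenate([r_ids, r_ids, r_ids]),
            np.concatenate([oB + 3 * pair_arr + 2, Ep, Eq]),
            np.concatenate([np.ones(npair_rows), -np.ones(npair_rows), -np.ones(npair_rows)]),
            -1.0,
            np.inf,
            npair_rows,
        )
        # no conflicting pair: the three witnesses never all fire
        r_ids = np.arange(P)
        add_block(
            np.concatenate([r_ids, r_ids, r_ids]),
            np.concatenate([oB + 3 * r_ids, oB + 3 * r_ids + 1, oB + 3 * r_ids + 2]),
            np.ones(3 * P),
            -np.inf,
            2.0,
            P,
        )

    if use_u and nU:
        # u(j) >= E(c, j) for every cell: u marks a loss column as used
        c_arr = np.repeat(np.arange(n), nU)
        l_arr = np.tile(np.arange(nU), n)
        nrows = n * nU
        r_ids = np.arange(nrows)
        add_block(
            np.concatenate([r_ids, r_ids]),
            np.concatenate([oU + l_arr, c_arr * K + loss_cols[l_arr]]),
            np.concatenate([np.ones(nrows), -np.ones(nrows)]),
            0.0,
            np.inf,
            nrows,
        )
        if max_losses is not None:
            add_block(
                np.zeros(nU, dtype=np.int64),
                oU + np.arange(nU),
                np.ones(nU),
                -np.inf,
                float(max_losses),
                1,
            )
        if symmetry_breaking and k >= 2:
            sym_r, sym_c, sym_d = [], [], []
            rr = 0
            for rank, j in enumerate(loss_cols):
                col = columns[j]
                if col.copy >= 2:
                    prev_rank = rank - 1  # copies of one mutation are consecutive
                    sym_r += [rr, rr]
                    sym_c += [oU + rank, oU + prev_rank]
                    sym_d += [1.0, -1.0]
                    rr += 1
            if rr:
                add_block(
                    np.array(sym_r),
                    np.array(sym_c),
                    np.array(sym_d),
                    -np.inf,
                    0.0,
                    rr,
                )

    A = sp.csr_matrix(
        (
            np.concatenate(data),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(row_base, nvars),
    )
    slope, intercept = objective_coefficients(I, rates)
    c_obj = np.zeros(nvars)
    c_obj[oF : oF + nF] = -slope.ravel()  # maximize likelihood => minimize -slope.F
    if sparsity_weight:
        c_obj[:nE] += float(sparsity_weight)
    return IlpModel(
        I=I,
        rates=rates,
        k=k,
        columns=columns,
        c=c_obj,
        A=A,
        lb=np.concatenate(lbs),
        ub=np.concatenate(ubs),
        constant=float(intercept.sum()),
        sparsity_weight=float(sparsity_weight),
        max_losses=max_losses,
        offsets={"E": 0, "F": oF, "B": oB, "u": oU},
    )


def start_trees(I: SCSMatrix):
    """Basic feasible start trees for the MIP-start heuristic.

    A primal start only needs to be feasible and cheap — the tree search is
    the refinement stage's job — so the candidates are the canonical
    trivial topologies: the empty (root-only) tree, the star of all
    mutations, and the prevalence-ordered chain.  All are loss-free, hence
    feasible for every Dollo(k) model and any loss cap.
    """
    from .extended import Gain
    from .tree import PhyloTree

    prevalence = (I.entries == 1).sum(axis=0)
    order = sorted(range(I.n_mutations), key=lambda j: (-int(prevalence[j]), j))
    empty = PhyloTree()
    star = PhyloTree()
    for mut in order:
        star.add_node(Gain(mut), star.root)
    chain = PhyloTree()
    cur = chain.root
    for mut in order:
        cur = chain.add_node(Gain(mut), cur)
    return [empty, star, chain]


def _heuristic_solution(model: IlpModel) -> tuple[ExtendedMatrix, np.ndarray, float]:
    """Best feasible (E, F, min-sense objective) among the basic start trees."""
    from .tree import best_attachment, extended_matrix_from_tree, genotype_matrix

    best = None
    for tree in start_trees(model.I):
        attachment, score = best_attachment(tree, model.I, model.rates)
        if best is None or score > best[2]:
            best = (tree, attachment, score)
    tree, attachment, _ = best
    E = extended_matrix_from_tree(tree, attachment, model.I.n_mutations, model.k)
    F = genotype_matrix(tree, attachment, model.I.n_mutations)
    ll = matrix_log_likelihood(model.I, F, model.rates)
    obj_min = -(ll - model.constant) + model.sparsity_weight * float(E.entries.sum())
    return E, F, obj_min


def solve(
    model: IlpModel,
    timeout: float | None = None,
    seed: int | None = None,
    threads: int | None = None,
    solver: str = "highs",
    primal_heuristic: bool = True,
) -> IlpSolution:
    """Solve the model, returning the incumbent if a timeout halts the search.

    With ``primal_heuristic`` (the default), a greedy feasible solution is
    constructed whenever the solver stops without an optimality proof, and
    the better of the two is returned — the usual MIP-start remedy for
    solvers whose own primal heuristics start late on large models.

    The returned solution always satisfies the structural invariants: the
    completed extended matrix is conflict-free and reproduces the genotype
    matrix entry-wise, and ``objective`` is the log-likelihood recomputed
    from the genotypes (checked against the solver's value to 1e-6).
    """
    backend = get_solver(solver)
    raw: RawSolution | None
    try:
        raw = backend.solve(
            model.c,
            model.A,
            model.lb,
            model.ub,
            timeout=timeout,
            seed=seed,
            threads=threads,
        )
    except NoIncumbentError:
        if not primal_heuristic:
            raise
        raw = None
    if raw is not None and raw.infeasible:
        return IlpSolution(status="infeasible")
    n, m = model.I.n_cells, model.I.n_mutations
    K = len(model.columns)
    E_star = F = None
    if raw is not None:
        E_entries = raw.x[: n * K].reshape(n, K)
        F = raw.x[model.offsets["F"] : model.offsets["F"] + n * m].reshape(n, m)
        E_star = ExtendedMatrix(columns=list(model.columns), entries=E_entries)
        objective = matrix_log_likelihood(model.I, F, model.rates)
        solver_ll = (
            model.constant - raw.objective + model.sparsity_weight * float(E_entries.sum())
        )
        if abs(solver_ll - objective) > 1e-6:
            raise RuntimeError(
                f"objective mismatch: solver reports {solver_ll}, recomputation "
                f"from genotypes gives {objective}"
            )
    if primal_heuristic and (raw is None or not raw.proven_optimal):
        E_h, F_h, obj_h = _heuristic_solution(model)
        if raw is None or obj_h < raw.objective:
            E_star, F = E_h, F_h
            objective = matrix_log_likelihood(model.I, F, model.rates)
    if not is_conflict_free(E_star):
        raise RuntimeError("solver returned a conflicting extended matrix")
    if not check_dollo_completion(E_star, model.I, F):
        raise RuntimeError("solver solution violates the gain/loss linking")
    status = "optimal" if (raw is not None and raw.proven_optimal) else "feasible-timeout"
    return IlpSolution(status=status, E_star=E_star, F_star=F, objective=objective)
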