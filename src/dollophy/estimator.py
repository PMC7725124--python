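"""scikit-learn-style front end for the full inference pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .error_model import ErrorRates
from .hillclimb import HillClimbConfig, hill_climb
from .ilp import build_model, solve
from .matrix import MISSING, SCSMatrix
from .tree import best_attachment, genotype_matrix, tree_from_extended_matrix


class DolloPhylogeny(BaseEstimator):
    """Infer a Dollo(k) tumor phylogeny from a noisy single-cell matrix.

    ``fit`` takes a cells x mutations array over {0, 1, 2} (or NaN), where
    0/1 are absent/present calls, and 2 or NaN marks a missing entry.  The
    maximum-likelihood ILP produces a conflict-free completed gain/loss
    matrix; the corresponding tree is extracted and optionally refined by
    randomized SPR hill climbing.

    Parameters
    ----------
    alpha, beta:
        False-negative and false-positive rates of the observations.
    k:
        Maximum number of losses per mutation (Dollo parameter).
    max_losses:
        Optional cap on the total number of realized loss columns.
    timeout:
        Solver time limit in seconds; the incumbent is kept when it fires.
    hill_climb:
        Whether to run the SPR refinement after the ILP.
    neighbor_samples, max_iterations:
        Hill-climbing width and length.
    sparsity_weight:
        Tiny per-entry penalty on the completed matrix; a secondary
        parsimony preference that never outweighs a genotype flip.

    Attributes
    ----------
    tree_ : PhyloTree
        The inferred phylogeny (post hill climbing when enabled).
    attachment_ : CellAttachment
        Likelihood-optimal node assignment of each cell.
    F_ : ndarray
        Predicted complete genotype matrix.
    log_likelihood_ : float
        Log-likelihood of the observations given ``F_``.
    ilp_objective_ : float
        Log-likelihood of the ILP solution before refinement.
    solver_status_ : str
        ``"optimal"`` or ``"feasible-timeout"``.
    n_losses_ : int
        Number of loss nodes in ``tree_``.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        beta: float = 1e-4,
        k: int = 1,
        max_losses: int | None = None,
        timeout: float | None = None,
        hill_climb: bool = True,
        neighbor_samples: int = 30,
        max_iterations: int = 100,
        solver: str = "highs",
        sparsity_weight: float = 1e-6,
        random_state: int | None = None,
    ) -> None:
        self.alpha = alpha
        self.beta = beta
        self.k = k
        self.max_losses = max_losses
        self.timeout = timeout
        self.hill_climb = hill_climb
        self.neighbor_samples = neighbor_samples
        self.max_iterations = max_iterations
        self.solver = solver
        self.sparsity_weight = sparsity_weight
        self.random_state = random_state

    def fit(self, X, y=None) -> "DolloPhylogeny":
        I = self._as_matrix(X)
        rates = ErrorRates(alpha=self.alpha, beta=self.beta)
        model = build_model(
            I,
            rates,
            k=self.k,
            max_losses=self.max_losses,
            sparsity_weight=self.sparsity_weight,
        )
        solution = solve(
            model, timeout=self.timeout, seed=self.random_state, solver=self.solver
        )
        if solution.status == "infeasible":
            raise RuntimeError(
                "model infeasible: the max_losses cap is over-constrained"
            )
        self.solver_status_ = solution.status
        self.ilp_objective_ = solution.objective
        tree = tree_from_extended_matrix(solution.E_star)
        if self.hill_climb and self.max_iterations > 0:
            cfg = HillClimbConfig(
                neighbor_samples=self.neighbor_samples,
                max_iterations=self.max_iterations,
                seed=self.random_state,
            )
            tree, attachment, score = hill_climb(tree, I, rates, cfg)
        else:
            attachment, score = best_attachment(tree, I, rates)
        self.tree_ = tree
        self.attachment_ = attachment
        self.log_likelihood_ = score
        self.F_ = genotype_matrix(tree, attachment, I.n_mutations)
        self.n_losses_ = tree.n_losses()
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the predicted complete genotype matrix."""
        return self.fit(X).F_

    @staticmethod
    def _as_matrix(X) -> SCSMatrix:
        if isinstance(X, SCSMatrix):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-D cells x mutations array")
        out = np.where(np.isnan(arr), float(MISSING), arr).astype(np.int8)
        return SCSMatrix(out)
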