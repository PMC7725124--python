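"""Observation error model for single-cell genotype calls.

A true genotype ``E[c,m]`` is observed through a noisy channel with a
false-negative rate ``alpha`` (a present mutation read as absent, chiefly
allelic dropout) and a false-positive rate ``beta``:

    P(I=1 | E=1) = 1 - alpha      P(I=0 | E=1) = alpha
    P(I=1 | E=0) = beta           P(I=0 | E=0) = 1 - beta

Missing entries carry no information and contribute exactly 0 to the
log-likelihood.  Because each predicted entry is binary, every per-entry
log-probability is an affine function of the predicted value, which is what
lets the likelihood enter a linear objective: this module also produces
those (slope, intercept) coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, SCSMatrix

#: Error rates are clamped to this open interval before taking logs so that
#: nominally noise-free configurations stay numerically usable.
RATE_FLOOR = 1e-9


@dataclass
class ErrorRates:
    """Global false-negative/false-positive rates, with optional per-entry grids.

    ``alpha_grid`` / ``beta_grid`` (cells x mutations), when given, override
    the global rates entry-wise — the non-uniform variant of the model where
    each (cell, mutation) pair has its own channel.
    """

    alpha: float
    beta: float
    alpha_grid: np.ndarray | None = None
    beta_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
            setattr(self, name, float(np.clip(v, RATE_FLOOR, 1.0 - RATE_FLOOR)))
        for name in ("alpha_grid", "beta_grid"):
            g = getattr(self, name)
            if g is not None:
                setattr(
                    self,
                    name,
                    np.clip(np.asarray(g, dtype=float), RATE_FLOOR, 1.0 - RATE_FLOOR),
                )

    def rates_at(self, cell: int, mutation: int) -> tuple[float, float]:
        a = self.alpha if self.alpha_grid is None else self.alpha_grid[cell, mutation]
        b = self.beta if self.beta_grid is None else self.beta_grid[cell, mutation]
        return float(a), float(b)

    def grids(self, n_cells: int, n_mutations: int) -> tuple[np.ndarray, np.ndarray]:
        """Dense (alpha, beta) grids of the requested shape."""
        shape = (n_cells, n_mutations)
        a = np.full(shape, self.alpha) if self.alpha_grid is None else self.alpha_grid
        b = np.full(shape, self.beta) if self.beta_grid is None else self.beta_grid
        if a.shape != shape or b.shape != shape:
            raise ValueError("override grid shape does not match the matrix")
        return a, b


def entry_log_prob(
    observed: int, predicted: int, rates: ErrorRates, cell: int = 0, mutation: int = 0
) -> float:
    """log P(observed | predicted) for one entry; exactly 0 for MISSING."""
    if observed == MISSING:
        return 0.0
    if predicted not in (0, 1) or observed not in (0, 1):
        raise ValueError(f"invalid states observed={observed}, predicted={predicted}")
    alpha, beta = rates.rates_at(cell, mutation)
    if predicted == 1:
        return float(np.log(1.0 - alpha)) if observed == 1 else float(np.log(alpha))
    return float(np.log(beta)) if observed == 1 else float(np.log(1.0 - beta))


def matrix_log_likelihood(I: SCSMatrix, F: np.ndarray, rates: ErrorRates) -> float:
    """Total log-likelihood of observing ``I`` given predicted genotypes ``F``.

    Equals the log of the product of the per-entry channel probabilities,
    restricted to known entries of ``I``.
    """
    F = np.asarray(F)
    if F.shape != I.entries.shape:
        raise ValueError(f"shape mismatch: I is {I.entries.shape}, F is {F.shape}")
    slope, intercept = objective_coefficients(I, rates)
    return float(np.sum(slope * F) + np.sum(intercept))


def objective_coefficients(
    I: SCSMatrix, rates: ErrorRates
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry affine coefficients of the log-likelihood in the predicted value.

    Returns ``(slope, intercept)`` arrays such that, for F in {0, 1},
    ``slope * F + intercept`` equals :func:`entry_log_prob`:

    * observed 1:  slope = log((1-alpha)/beta),   intercept = log(beta)
    * observed 0:  slope = log(alpha/(1-beta)),   intercept = log(1-beta)
    * missing:     slope = intercept = 0
    """
    a, b = rates.grids(I.n_cells, I.n_mutations)
    slope = np.zeros(I.entries.shape, dtype=float)
    intercept = np.zeros(I.entries.shape, dtype=float)
    ones = I.entries == 1
    zeros = I.entries == 0
    slope[ones] = np.log((1.0 - a[ones]) / b[ones])
    intercept[ones] = np.log(b[ones])
    slope[zeros] = np.log(a[zeros] / (1.0 - b[zeros]))
    intercept[zeros] = np.log(1.0 - b[zeros])
    return slope, intercept
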