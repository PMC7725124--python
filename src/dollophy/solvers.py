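"""Pluggable MILP solver backends.

The formulation only needs a plain branch-and-bound MILP solver: binary
variables, sparse linear constraints, a linear objective, a time limit, and
access to the incumbent when the limit halts the search before optimality.
Backends implement :class:`SolverBackend`; the default adapter drives HiGHS
through :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp


class SolverUnavailableError(RuntimeError):
    """The requested backend is not installed/usable."""


class NoIncumbentError(RuntimeError):
    """The time limit expired before any feasible solution was found."""


@dataclass
class RawSolution:
    x: np.ndarray  # variable values, already rounded to {0, 1}
    objective: float  # objective value in the *minimization* sense
    proven_optimal: bool
    infeasible: bool = False


class SolverBackend(ABC):
    """Minimal MILP interface: minimize c @ x s.t. lb <= A x <= ub, x binary."""

    @abstractmethod
    def solve(
        self,
        c: np.ndarray,
        A: sp.spmatrix,
        lb: np.ndarray,
        ub: np.ndarray,
        timeout: float | None = None,
        seed: int | None = None,
        threads: int | None = None,
    ) -> RawSolution: ...


class HighsBackend(SolverBackend):
    """HiGHS via ``scipy.optimize.milp``.

    HiGHS runs deterministically here; ``seed`` and ``threads`` are accepted
    for interface compatibility but the scipy wrapper exposes neither knob.
    """

    def solve(self, c, A, lb, ub, timeout=None, seed=None, threads=None):
        options: dict = {"mip_rel_gap": 0.0}
        if timeout is not None:
            options["time_limit"] = float(timeout)
        res = milp(
            c=c,
            constraints=LinearConstraint(A, lb, ub),
            integrality=np.ones(c.shape[0]),
            bounds=Bounds(0.0, 1.0),
            options=options,
        )
        if res.status == 2:
            return RawSolution(
                x=np.zeros(0), objective=np.inf, proven_optimal=False, infeasible=True
            )
        if res.x is None:
            raise NoIncumbentError(
                "no feasible solution found within the time limit; rerun with a "
                "longer timeout"
            )
        x = np.rint(np.asarray(res.x)).astype(np.int8)
        return RawSolution(
            x=x, objective=float(res.fun), proven_optimal=(res.status == 0)
        )


_BACKENDS: dict[str, type[SolverBackend]] = {"highs": HighsBackend}


def get_solver(name: str) -> SolverBackend:
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise SolverUnavailableError(
            f"unknown solver backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls()


def register_backend(name: str, cls: type[SolverBackend]) -> None:
    _BACKENDS[name] = cls
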