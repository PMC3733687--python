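"""Thin mixed-integer linear programming backend.

The path solver only needs: binary and continuous variables, linear
constraints with two-sided bounds, a linear objective, and a status that
distinguishes a proven-infeasible model from a time-limit hit. The default
backend is HiGHS through :func:`scipy.optimize.milp`; alternative backends
implement :class:`MilpBackend`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNDETERMINED = "undetermined"


class BackendError(RuntimeError):
    """Solver backend failed for a reason other than infeasibility."""


class UndeterminedError(RuntimeError):
    """The solver hit its time limit before proving optimality or infeasibility.

    Disconnection is a scientific claim; a timeout must never be reported as
    one, so callers receive this distinct error instead of ``infeasible``.
    """


@dataclass
class MilpResult:
    status: str
    objective: float | None
    values: np.ndarray | None
    message: str = ""


@dataclass(frozen=True)
class MilpProblem:
    """Standard-form MILP: min c'x s.t. row_lb <= A x <= row_ub, lb <= x <= ub."""

    c: np.ndarray
    A: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray  # 1 for integer (binary via bounds), 0 continuous


class MilpBackend:
    def solve(self, problem: MilpProblem, time_limit: float | None = None) -> MilpResult:
        raise NotImplementedError


class ScipyHighsBackend(MilpBackend):
    """HiGHS via scipy.optimize.milp (deterministic, single-threaded)."""

    def __init__(self, mip_rel_gap: float = 0.0, presolve: bool = True):
        self.mip_rel_gap = mip_rel_gap
        self.presolve = presolve

    def solve(self, problem: MilpProblem, time_limit: float | None = None) -> MilpResult:
        options: dict = {"mip_rel_gap": self.mip_rel_gap, "presolve": self.presolve}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=problem.c,
            constraints=[LinearConstraint(problem.A, problem.row_lb, problem.row_ub)],
            integrality=problem.integrality,
            bounds=Bounds(problem.lb, problem.ub),
            options=options,
        )
        # scipy milp status codes: 0 optimal, 1 iteration/time limit,
        # 2 infeasible, 3 unbounded, 4 other
        if res.status == 0:
            return MilpResult(OPTIMAL, float(res.fun), np.asarray(res.x), res.message)
        if res.status == 2:
            return MilpResult(INFEASIBLE, None, None, res.message)
        if res.status == 1:
            return MilpResult(UNDETERMINED, None, None, res.message)
        raise BackendError(f"MILP backend failure (status {res.status}): {res.message}")


DEFAULT_BACKEND = ScipyHighsBackend()
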