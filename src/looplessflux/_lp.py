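"""Thin LP layer over scipy's HiGHS interface.

All linear programs in the package go through :func:`solve_lp` so that solver
failures surface as :class:`~looplessflux.errors.SolverError` and infeasibility
as a structured result rather than an exception deep inside a sampler loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError

__all__ = ["LPResult", "solve_lp"]


@dataclass
class LPResult:
    feasible: bool
    x: np.ndarray | None
    fun: float | None


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    lb: np.ndarray | float = -np.inf,
    ub: np.ndarray | float = np.inf,
) -> LPResult:
    """Minimize ``c @ x`` subject to equality/inequality constraints and box bounds.

    Returns an :class:`LPResult` with ``feasible=False`` for proven primal
    infeasibility. Any other solver failure (numerical breakdown, iteration
    limit, unboundedness where it should not occur) raises ``SolverError``.
    """
    n = len(c)
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (n,))
    ub = np.broadcast_to(np.asarray(ub, dtype=float), (n,))
    bounds = np.column_stack([lb, ub])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        # tight primal tolerance: downstream feasibility audits are at 1e-9
        options={"primal_feasibility_tolerance": 1e-10},
    )
    if res.status == 0:
        return LPResult(True, np.asarray(res.x, dtype=float), float(res.fun))
    if res.status == 2:  # proven infeasible
        return LPResult(False, None, None)
    raise SolverError(f"LP solver failed with status {res.status}: {res.message}")
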