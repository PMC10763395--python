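"""Reduce a model to its samplable flux space.

The pipeline is: flux variability analysis (FVA) to find blocked reactions,
removal of blocked reactions and orphaned metabolites, construction of two
null-space bases — an orthonormal basis ``N_perp`` of ``null(S)`` (used for
drift control and isotropic directions) and a sparse basis ``N_int`` of
``null(S_int)`` over the internal reactions (used by the loop detector) —
and generation of one feasible loopless starting point.

The sparse internal basis is computed by exact rational row reduction
followed by a pairwise support-minimization pass. This keeps the only
property downstream code needs — a spanning, sparse null basis — without the
NP-hard search for a globally minimal-support basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import sympy

from ._lp import solve_lp
from .errors import (
    DegenerateSpaceError,
    EmptySpaceError,
    InfeasibleModelError,
)
from .loopcheck import LoopChecker
from .model_io import MetabolicModel

__all__ = [
    "FluxSpace",
    "flux_variability",
    "remove_blocked",
    "sparse_null_basis",
    "orthonormal_null_basis",
    "find_loopless_point",
    "build_flux_space",
    "TOL_EQ",
    "TOL_ZERO",
]

TOL_EQ = 1e-9  #: equality (mass-balance) tolerance
TOL_ZERO = 1e-9  #: flux magnitude below which a flux counts as zero


@dataclass
class FluxSpace:
    """A preprocessed, samplable flux space.

    Invariants: ``||S @ N_perp||_max <= tol_eq``; ``||S_int @ N_int||_max <=
    tol_eq``; ``lb <= v0 <= ub``; ``||S @ v0||_max <= tol_eq``; ``v0`` is
    loopless.
    """

    model: MetabolicModel  # reduced model
    N_perp: np.ndarray  # orthonormal basis of null(S), shape (n, d)
    N_int: np.ndarray  # sparse basis of null(S_int), shape (n_int, c)
    v0: np.ndarray  # one feasible loopless point
    tol_eq: float = TOL_EQ
    tol_zero: float = TOL_ZERO
    index_map: np.ndarray | None = None  # reduced index -> original index

    @property
    def dim(self) -> int:
        """Dimension of the affine subspace being sampled."""
        return self.N_perp.shape[1]

    @property
    def n_loops(self) -> int:
        """Number of independent internal cycles (columns of ``N_int``)."""
        return self.N_int.shape[1]

    def make_checker(self) -> LoopChecker:
        return LoopChecker(self.N_int, self.model.internal_mask, self.tol_zero)

    def embed_internal(self, g_int: np.ndarray) -> np.ndarray:
        """Lift an internal-reaction vector to full reaction length."""
        g = np.zeros(self.model.n_reactions)
        g[self.model.internal_mask] = g_int
        return g


def flux_variability(
    model: MetabolicModel, tol: float = TOL_EQ
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction LP minimum and maximum of ``v_j`` over the flux polytope.

    This is plain FVA over the convex relaxation: the loop law is ignored, so
    a reaction inside a cycle reports the full range its bounds allow.
    """
    m, n = model.S.shape
    A_eq = model.S if m else None
    b_eq = np.zeros(m) if m else None
    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo = solve_lp(c, A_eq=A_eq, b_eq=b_eq, lb=model.lb, ub=model.ub)
        if not lo.feasible:
            raise InfeasibleModelError(
                "flux polytope is empty; check bounds "
                f"(lb={model.lb.min():g}..{model.lb.max():g}, "
                f"ub={model.ub.min():g}..{model.ub.max():g})"
            )
        hi = solve_lp(-c, A_eq=A_eq, b_eq=b_eq, lb=model.lb, ub=model.ub)
        vmin[j] = lo.fun
        vmax[j] = -hi.fun
    # LP round-off can invert the pair by ~1e-12
    vmin, vmax = np.minimum(vmin, vmax), np.maximum(vmin, vmax)
    return vmin, vmax


def remove_blocked(
    model: MetabolicModel,
    fva_result: tuple[np.ndarray, np.ndarray],
    tol_zero: float = TOL_ZERO,
) -> tuple[MetabolicModel, np.ndarray]:
    """Drop reactions that cannot carry flux, and metabolites they orphan.

    Returns the reduced model and an ``index_map`` such that reduced reaction
    ``i`` is original reaction ``index_map[i]``. Idempotent: a second pass
    removes nothing.
    """
    vmin, vmax = fva_result
    keep = (np.abs(vmin) > tol_zero) | (np.abs(vmax) > tol_zero)
    if not np.any(keep):
        raise EmptySpaceError("all reactions are blocked; nothing to sample")
    index_map = np.where(keep)[0]
    S = model.S[:, keep]
    keep_met = np.any(S != 0.0, axis=1)
    reduced = MetabolicModel(
        S=S[keep_met, :],
        lb=model.lb[keep],
        ub=model.ub[keep],
        rxn_ids=[model.rxn_ids[j] for j in index_map],
        met_ids=[m for m, k in zip(model.met_ids, keep_met) if k],
        internal_mask=model.internal_mask[keep],
        objective=None if model.objective is None else model.objective[keep],
    )
    return reduced, index_map


def _rational_matrix(A: np.ndarray) -> sympy.Matrix:
    return sympy.Matrix(
        [[sympy.nsimplify(x, rational=True) for x in row] for row in A]
    )


def sparse_null_basis(S_int: np.ndarray, tol: float = TOL_ZERO) -> np.ndarray:
    """Sparse basis of ``null(S_int)`` by rational row reduction.

    Row reduction over the rationals gives an exact spanning basis; a greedy
    pairwise-elimination pass then shrinks column supports (replace ``x_i`` by
    ``x_i - (x_i[k]/x_j[k]) x_j`` whenever that strictly reduces the support
    — span-preserving by construction). Supports are inclusion-minimal within
    the returned basis, not globally minimal. Columns are scaled so the
    largest-magnitude entry is 1; entries below ``tol`` are set to exact zero.
    """
    S_int = np.atleast_2d(np.asarray(S_int, dtype=float))
    n_int = S_int.shape[1]
    if n_int == 0:
        return np.zeros((0, 0))
    basis = _rational_matrix(S_int).nullspace()
    if not basis:
        return np.zeros((n_int, 0))
    vecs = [sympy.Matrix(b) for b in basis]

    def support(x):
        return frozenset(i for i in range(n_int) if x[i] != 0)

    improved = True
    while improved:
        improved = False
        for i in range(len(vecs)):
            for j in range(len(vecs)):
                if i == j:
                    continue
                si, sj = support(vecs[i]), support(vecs[j])
                for k in si & sj:
                    cand = vecs[i] - (vecs[i][k] / vecs[j][k]) * vecs[j]
                    if cand.is_zero_matrix:
                        continue
                    if len(support(cand)) < len(si):
                        vecs[i] = cand
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break

    cols = []
    for x in vecs:
        arr = np.array([float(v) for v in x], dtype=float)
        arr = arr / np.max(np.abs(arr))
        arr[np.abs(arr) < tol] = 0.0
        cols.append(arr)
    return np.column_stack(cols)


def orthonormal_null_basis(S: np.ndarray, tol_eq: float = TOL_EQ) -> np.ndarray:
    """Orthonormal basis of ``null(S)`` via SVD; identity if there are no rows."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    if m == 0 or not np.any(S):
        return np.eye(n)
    N = scipy.linalg.null_space(S)
    if N.shape[1] == 0:
        raise DegenerateSpaceError(
            "stoichiometric matrix has full column rank: the mass-balanced "
            "space is {0}; nothing to sample"
        )
    assert np.max(np.abs(S @ N)) <= max(tol_eq, 1e-10 * np.max(np.abs(S)))
    return N


def _cycle_free(
    model: MetabolicModel, v_hat: np.ndarray, tol_zero: float
) -> np.ndarray:
    """Strip internal cycles from ``v_hat`` by the cycle-free LP.

    Holds every exchange flux fixed, restricts each internal flux to the
    closed interval between 0 and its current value (so no sign flips), and
    minimizes total internal flux magnitude. The optimum carries the same net
    conversion with all removable circulation cancelled.
    """
    n = model.n_reactions
    lb = v_hat.copy()
    ub = v_hat.copy()
    obj = np.zeros(n)
    for j in np.where(model.internal_mask)[0]:
        if v_hat[j] > tol_zero:
            lb[j], ub[j], obj[j] = 0.0, v_hat[j], 1.0
        elif v_hat[j] < -tol_zero:
            lb[j], ub[j], obj[j] = v_hat[j], 0.0, -1.0
        else:
            lb[j] = ub[j] = 0.0
    m = model.n_metabolites
    res = solve_lp(
        obj,
        A_eq=model.S if m else None,
        b_eq=np.zeros(m) if m else None,
        lb=lb,
        ub=ub,
    )
    if not res.feasible:  # v_hat itself is feasible, so this cannot happen
        raise InfeasibleModelError("cycle-free LP infeasible from a feasible point")
    return res.x


def find_loopless_point(
    model: MetabolicModel,
    checker: LoopChecker,
    rng: np.random.Generator,
    tol_zero: float = TOL_ZERO,
    max_tries: int = 50,
    objective: np.ndarray | None = None,
    N_perp: np.ndarray | None = None,
) -> np.ndarray:
    """One nonzero feasible loopless flux vector, via random-objective LP.

    Strategy: maximize a random +-1 objective over the convex polytope (an
    over-dispersed vertex), cancel any internal cycles with the cycle-free LP,
    and verify looplessness with the detector. Retries with fresh objectives;
    if every attempt yields only the zero vector or a loopy point, the
    loopless space is declared degenerate.

    When ``N_perp`` is given, the LP solution is orthogonally projected onto
    ``null(S)`` before verification, squeezing the solver's equality residual
    (~1e-10) down to SVD accuracy so downstream audits at 1e-9 hold.
    """
    m, n = model.S.shape
    A_eq = model.S if m else None
    b_eq = np.zeros(m) if m else None
    for attempt in range(max_tries):
        if objective is not None and attempt == 0:
            c = -objective
        else:
            c = -rng.choice([-1.0, 1.0], size=n)
        res = solve_lp(c, A_eq=A_eq, b_eq=b_eq, lb=model.lb, ub=model.ub)
        if not res.feasible:
            raise InfeasibleModelError("flux polytope is empty")
        v = _cycle_free(model, res.x, tol_zero)
        if N_perp is not None:
            v = N_perp @ (N_perp.T @ v)
            v = np.clip(v, model.lb, model.ub)
        if np.max(np.abs(v)) <= tol_zero:
            continue
        if not checker(v):
            return v
    raise DegenerateSpaceError(
        f"no nonzero loopless point found in {max_tries} random-objective tries"
    )


def build_flux_space(
    model: MetabolicModel,
    tol_eq: float = TOL_EQ,
    tol_zero: float = TOL_ZERO,
    seed: int | np.random.Generator = 0,
) -> FluxSpace:
    """Full preprocessing pipeline: FVA -> reduce -> bases -> seed point."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fva = flux_variability(model, tol_eq)
    reduced, index_map = remove_blocked(model, fva, tol_zero)
    N_perp = orthonormal_null_basis(reduced.S, tol_eq)
    N_int = sparse_null_basis(reduced.S_int, tol_zero)
    checker = LoopChecker(N_int, reduced.internal_mask, tol_zero)
    v0 = find_loopless_point(reduced, checker, rng, tol_zero, N_perp=N_perp)
    return FluxSpace(
        model=reduced,
        N_perp=N_perp,
        N_int=N_int,
        v0=v0,
        tol_eq=tol_eq,
        tol_zero=tol_zero,
        index_map=index_map,
    )
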