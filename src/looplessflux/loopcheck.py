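"""Detection of active thermodynamically infeasible loops in a flux vector.

A steady-state flux vector ``v`` carries an active loop iff a nonzero internal
circulation ``g`` exists with ``S_int @ g = 0`` whose sign pattern is
compatible with that of ``v`` on the internal reactions: ``g_i = 0`` wherever
``v_i`` is (numerically) zero, and ``g_i`` shares the sign of ``v_i``
elsewhere. Such a ``g`` is a nonnegative combination of type-III extreme
pathways — internal cycles with no net conversion — and its presence violates
the loop law (the flux analogue of Kirchhoff's second law). The test is
purely topological: it depends on ``v`` only through its sign pattern.

Two independent implementations are provided:

* :func:`has_active_loop` — an LP feasibility test in null-space coordinates,
  used by the samplers (with verdicts cached per sign pattern).
* :func:`brute_force_loop_oracle` — exhaustive support enumeration on small
  instances, used to validate the LP formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._lp import solve_lp
from .errors import LooplessFluxError

__all__ = [
    "SignPattern",
    "LoopOracleResult",
    "sign_pattern",
    "has_active_loop",
    "LoopChecker",
    "brute_force_loop_oracle",
]


@dataclass
class SignPattern:
    """Sign pattern of a flux vector over the internal reactions."""

    pattern: np.ndarray  # values in {-1, 0, +1}, one per internal reaction
    tol_zero: float


@dataclass
class LoopOracleResult:
    has_loop: bool
    witness: np.ndarray | None  # internal circulation g, or None
    extreme_rays: list[np.ndarray]  # sign-compatible rays with minimal support


def sign_pattern(
    v: np.ndarray, internal_mask: np.ndarray, tol_zero: float = 1e-9
) -> SignPattern:
    """Map internal fluxes to {-1, 0, +1}; magnitudes below ``tol_zero`` are 0.

    The tolerance decides borderline loop verdicts and is therefore recorded
    in the result and propagated into archive metadata.
    """
    v_int = np.asarray(v, dtype=float)[np.asarray(internal_mask, dtype=bool)]
    pat = np.sign(v_int)
    pat[np.abs(v_int) <= tol_zero] = 0.0
    return SignPattern(pattern=pat.astype(np.int8), tol_zero=tol_zero)


def _loop_lp(N_int: np.ndarray, pattern: np.ndarray) -> np.ndarray | None:
    """Feasibility LP for a sign-compatible circulation, in basis coordinates.

    Searches ``g = N_int @ alpha`` with ``g_i = 0`` where ``pattern_i = 0``,
    ``pattern_i * g_i >= 0`` elsewhere, normalized by
    ``sum_i pattern_i * g_i >= 1`` (any positive right-hand side is equivalent
    by scaling, and it makes "g nonzero" LP-expressible). Solving in the
    ``alpha`` coordinates uses c variables instead of n_int — mathematically
    identical and cheaper whenever the null space is low-dimensional.

    Returns the witness ``g`` or ``None`` if no such circulation exists.
    """
    c = N_int.shape[1]
    if c == 0:
        return None
    zero_rows = pattern == 0
    act_rows = ~zero_rows
    A_eq = N_int[zero_rows, :]
    b_eq = np.zeros(A_eq.shape[0])
    # pattern_i * g_i >= 0  ->  -(pattern_i * N_int[i]) @ alpha <= 0
    signed = pattern[act_rows, None] * N_int[act_rows, :]
    A_ub = -signed
    b_ub = np.zeros(A_ub.shape[0])
    # normalization: sum of signed active fluxes >= 1
    A_ub = np.vstack([A_ub, -signed.sum(axis=0, keepdims=True)])
    b_ub = np.append(b_ub, -1.0)
    res = solve_lp(
        np.zeros(c),
        A_eq=A_eq if A_eq.size else None,
        b_eq=b_eq if A_eq.size else None,
        A_ub=A_ub,
        b_ub=b_ub,
    )
    if not res.feasible:
        return None
    g = N_int @ res.x
    g[zero_rows] = 0.0  # enforce exact zeros against solver tolerance
    return g


class LoopChecker:
    """Cached loop detector bound to one null-space basis of ``S_int``.

    The verdict depends on ``v`` only through its internal sign pattern, so
    verdicts are memoized per pattern — on fixture-scale networks this turns
    the per-proposal LP into a dictionary lookup after warm-up.
    """

    def __init__(
        self, N_int: np.ndarray, internal_mask: np.ndarray, tol_zero: float = 1e-9
    ):
        self.N_int = np.asarray(N_int, dtype=float)
        self.internal_mask = np.asarray(internal_mask, dtype=bool)
        self.tol_zero = float(tol_zero)
        self._cache: dict[bytes, tuple[bool, np.ndarray | None]] = {}
        self.n_lp_calls = 0

    def check(self, v: np.ndarray) -> tuple[bool, np.ndarray | None]:
        """Return ``(has_loop, witness)`` for flux vector ``v``."""
        if self.N_int.shape[1] == 0:
            return False, None
        pat = sign_pattern(v, self.internal_mask, self.tol_zero).pattern
        if not np.any(pat):
            return False, None
        key = pat.tobytes()
        hit = self._cache.get(key)
        if hit is None:
            self.n_lp_calls += 1
            g = _loop_lp(self.N_int, pat)
            hit = (g is not None, g)
            self._cache[key] = hit
        return hit

    def __call__(self, v: np.ndarray) -> bool:
        return self.check(v)[0]


def has_active_loop(v, fluxspace) -> tuple[bool, np.ndarray | None]:
    """Does ``v`` contain an active internal loop? Returns (verdict, witness).

    ``fluxspace`` is any object exposing ``N_int`` (null basis of ``S_int``
    over the internal reactions), ``model.internal_mask`` and ``tol_zero`` —
    in practice a :class:`~looplessflux.preprocess.FluxSpace`.
    """
    checker = LoopChecker(
        fluxspace.N_int, fluxspace.model.internal_mask, fluxspace.tol_zero
    )
    return checker.check(v)


def brute_force_loop_oracle(
    v: np.ndarray,
    S_int: np.ndarray,
    internal_mask: np.ndarray | None = None,
    tol_zero: float = 1e-9,
    max_size: int = 12,
) -> LoopOracleResult:
    """Exhaustive loop detection by enumerating candidate cycle supports.

    For every nonempty subset ``T`` of the nonzero-pattern internal reactions,
    ask whether a circulation exists that is *strictly* active with the
    pattern's sign on all of ``T`` and zero elsewhere (an LP over the columns
    of ``T`` only, with per-coordinate constraints — a different formulation
    from the normalized one in :func:`has_active_loop`). A loop is present iff
    any subset admits one; inclusion-minimal feasible supports yield the
    type-III extreme rays compatible with ``v``.

    Only intended for small instances (``n_int <= max_size``).
    """
    S_int = np.atleast_2d(np.asarray(S_int, dtype=float))
    n_int = S_int.shape[1]
    if n_int > max_size:
        raise LooplessFluxError(
            f"brute-force oracle limited to {max_size} internal reactions, got {n_int}"
        )
    if internal_mask is None:
        v_int = np.asarray(v, dtype=float)
    else:
        v_int = np.asarray(v, dtype=float)[np.asarray(internal_mask, dtype=bool)]
    pat = np.sign(v_int)
    pat[np.abs(v_int) <= tol_zero] = 0.0
    support = np.where(pat != 0)[0]

    rays: list[np.ndarray] = []
    minimal_supports: list[frozenset] = []
    witness = None
    for size in range(1, len(support) + 1):
        for T in combinations(support, size):
            Tset = frozenset(T)
            if any(ms <= Tset for ms in minimal_supports):
                continue  # contains a smaller cycle already found
            cols = S_int[:, list(T)]
            # a strictly supported null vector needs a rank-deficient submatrix
            if np.linalg.matrix_rank(cols) == len(T):
                continue
            signs = pat[list(T)]
            # find x with S_int[:, T] @ x = 0 and sign_i * x_i >= 1 on all of T
            res = solve_lp(
                np.zeros(len(T)),
                A_eq=cols,
                b_eq=np.zeros(cols.shape[0]),
                A_ub=-np.diag(signs.astype(float)),
                b_ub=-np.ones(len(T)),
            )
            if res.feasible:
                g = np.zeros(n_int)
                g[list(T)] = res.x
                g /= np.max(np.abs(g))
                rays.append(g)
                minimal_supports.append(Tset)
                if witness is None:
                    witness = g
    return LoopOracleResult(
        has_loop=witness is not None, witness=witness, extreme_rays=rays
    )
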