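"""MCMC samplers over the (loopless) mass-balanced flux space.

Three samplers share one chord/shrink engine:

* :func:`run_adsb` — Adaptive Direction Sampling on a Box. Each of ``K``
  non-interacting chains carries a current set of ``k`` flux points. A step
  picks a current point ``v_c`` and two other distinct points ``v_1, v_2``
  from the set, moves along the chord through ``v_c`` parallel to
  ``u* = (v_1 - v_2)/||v_1 - v_2||`` (a difference of mass-balanced points,
  hence itself mass-balanced), draws a uniform step on the chord, and — when
  the target is the non-convex loopless space — rejects loop-active proposals
  by shrinking the chord toward ``v_c`` as in slice sampling. The accepted
  point replaces ``v_c`` in the set. Because directions are built from the
  current population, they adapt to the shape of the target region. The chain
  targets the uniform distribution as long as the set spans the space.

* :func:`run_hr` — classic Hit-and-Run on the convex polytope, isotropic
  directions in null-space coordinates. Optionally *marks* (never removes)
  samples that fail the loop test, mirroring the sample-then-verify protocol.

* :func:`run_ll_achrb` — loopless Artificial-Centering Hit-and-Run on a Box:
  directions from the running center of the current set through a random
  member. Not a Markov chain (the center depends on history); archives are
  flagged ``non_markovian``.

All samplers are deterministic given ``SamplerOptions.seed``; each chain owns
an independent seed-derived RNG stream, so results do not depend on whether
chains run sequentially or in parallel worker processes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from math import ceil
from pathlib import Path

import numpy as np

from .errors import InitializationError, StateCorruptionError
from .loopcheck import LoopChecker
from .preprocess import FluxSpace, find_loopless_point

__all__ = [
    "SamplerOptions",
    "ChainState",
    "Proposal",
    "SampleArchive",
    "initialize_chains",
    "chord_limits",
    "shrink_sample",
    "adsb_step",
    "run_adsb",
    "run_hr",
    "run_ll_achrb",
    "load_archive",
]

_DEGENERATE_DIRECTION = 1e-12


@dataclass
class SamplerOptions:
    """Run settings shared by all samplers.

    Defaults follow the benchmark protocol of the original method: 2*10^5
    final points, 100 attempted steps per stored point (thinning), and the
    first 2*10^4 stored points discarded as burn-in. ``k`` (points per chain,
    ADSB/ll-ACHRB only) defaults to ``min(2d+1, 50)`` for a d-dimensional
    space, which guarantees the spanning condition whenever it is attainable;
    ``K`` is the number of non-interacting chains.
    """

    n_samples: int = 200_000
    thinning: int = 100
    burn_in: int = 20_000
    K: int = 4
    k: int | None = None
    seed: int = 0
    eps_shrink: float = 1e-8  # relative to the initial chord width
    reproject_every: int = 1000
    target: str = "uniform"
    loopless_filter: bool = False  # HR only: mark loop-active samples
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.target != "uniform":
            raise ValueError("only the uniform target is supported")
        if self.K < 1 or self.thinning < 1 or self.n_samples < 1:
            raise ValueError("K, thinning and n_samples must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.k is not None and self.k < 3:
            raise ValueError("k must be >= 3 (current point plus two direction points)")

    def resolved_k(self, d: int) -> int:
        return self.k if self.k is not None else max(3, min(2 * d + 1, 50))


@dataclass
class ChainState:
    """Augmented sampler state: K chains of k current points each."""

    V: np.ndarray  # (K, k, n)
    t: int
    rng_streams: list[np.random.Generator]
    warnings: list[str] = field(default_factory=list)


@dataclass
class Proposal:
    u_star: np.ndarray
    lambda_range: tuple[float, float]
    lambda_star: float
    v_star: np.ndarray


@dataclass
class SampleArchive:
    """Thinned, burned-in flux samples plus provenance.

    ``samples`` has one row per stored draw; ``chain_index`` records the
    originating chain; ``meta`` carries options, tolerances, counters, wall
    time and any warnings so a run can be reproduced from the archive alone.
    """

    samples: np.ndarray  # (n_samples, n)
    chain_index: np.ndarray
    rxn_ids: list[str]
    options: SamplerOptions
    meta: dict

    def save(self, directory: str) -> None:
        """Write samples as CSV (reactions as named columns) + JSON sidecar."""
        import json

        import pandas as pd

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.samples, columns=self.rxn_ids)
        df.insert(0, "chain", self.chain_index)
        df.to_csv(out / "samples.csv", index=False)
        meta = dict(self.meta)
        meta["options"] = asdict(self.options)
        with open(out / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=_jsonify)

    @property
    def chains_array(self) -> np.ndarray:
        """Samples reshaped to (K, N, n); truncates to the shortest chain."""
        ids = np.unique(self.chain_index)
        per = [self.samples[self.chain_index == i] for i in ids]
        N = min(len(p) for p in per)
        return np.stack([p[:N] for p in per])


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_archive(directory: str) -> SampleArchive:
    import json

    import pandas as pd

    out = Path(directory)
    df = pd.read_csv(out / "samples.csv")
    with open(out / "metadata.json") as fh:
        meta = json.load(fh)
    opts = SamplerOptions(**meta.pop("options"))
    chain_index = df.pop("chain").to_numpy()
    return SampleArchive(
        samples=df.to_numpy(),
        chain_index=chain_index,
        rxn_ids=list(df.columns),
        options=opts,
        meta=meta,
    )


def chord_limits(
    v_c: np.ndarray,
    u_star: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Intersection of the line ``v_c + lambda*u`` with the bound box.

    Mass balance holds along the whole line whenever ``u`` lies in
    ``null(S)``, so the box is the only constraint. Components with
    ``|u_i| <= 1e-12`` impose none. The returned interval always contains 0.
    """
    if np.any(v_c < lb - tol) or np.any(v_c > ub + tol):
        worst = float(max(np.max(lb - v_c), np.max(v_c - ub)))
        raise StateCorruptionError(
            f"current point violates bounds by {worst:.3g}; sampler state corrupt"
        )
    active = np.abs(u_star) > _DEGENERATE_DIRECTION
    if not np.any(active):
        return 0.0, 0.0
    u = u_star[active]
    lo = (lb[active] - v_c[active]) / u
    hi = (ub[active] - v_c[active]) / u
    lam_lo = np.where(u > 0, lo, hi)
    lam_hi = np.where(u > 0, hi, lo)
    lam_min = float(np.max(lam_lo))
    lam_max = float(np.min(lam_hi))
    # v_c sits inside the box up to tol; clamp round-off so 0 is included
    return min(lam_min, 0.0), max(lam_max, 0.0)


def shrink_sample(
    v_c: np.ndarray,
    u_star: np.ndarray,
    lambda_range: tuple[float, float],
    loop_test,
    rng: np.random.Generator,
    eps_shrink: float,
) -> tuple[np.ndarray | None, int]:
    """Uniform draw on the chord with slice-sampling interval shrinkage.

    Draw ``lambda* ~ U(lmin, lmax)``; if the proposal passes ``loop_test``
    (returns False = no active loop) accept it, otherwise shrink the interval
    on the rejected side toward 0 (the current point) and redraw. Give up and
    return ``None`` once the interval is narrower than ``eps_shrink`` —
    retaining the current point, which preserves the invariant distribution
    for slice-type shrinkage. Returns ``(point_or_None, n_shrinks)``.
    """
    lam_min, lam_max = lambda_range
    n_shrinks = 0
    while (lam_max - lam_min) >= eps_shrink:
        lam = rng.uniform(lam_min, lam_max)
        v_star = v_c + lam * u_star
        if not loop_test(v_star):
            return v_star, n_shrinks
        n_shrinks += 1
        if lam > 0:
            lam_max = lam
        else:
            lam_min = lam
    return None, n_shrinks


def _span_rank(points: np.ndarray, tol: float = 1e-8) -> int:
    diffs = points[1:] - points[0]
    if diffs.size == 0:
        return 0
    scale = max(np.max(np.abs(diffs)), 1.0)
    return int(np.linalg.matrix_rank(diffs, tol=tol * scale))


def _diversify(
    points: np.ndarray,
    fs: FluxSpace,
    checker: LoopChecker,
    rng: np.random.Generator,
    need_rank: int,
    max_moves: int,
) -> np.ndarray:
    """Random-direction moves until the set's differences reach ``need_rank``.

    LP vertices from few distinct objectives can coincide (e.g. a 1-D flux
    line has two vertices, one of them zero); random chord moves inside the
    loopless space spread the set without leaving it.
    """
    d = fs.dim
    lb, ub = fs.model.lb, fs.model.ub
    for _ in range(max_moves):
        if _span_rank(points) >= need_rank:
            break
        i = int(rng.integers(len(points)))
        z = rng.standard_normal(d)
        u = fs.N_perp @ z
        norm = np.linalg.norm(u)
        if norm <= _DEGENERATE_DIRECTION:
            continue
        u /= norm
        lam_range = chord_limits(points[i], u, lb, ub)
        width = lam_range[1] - lam_range[0]
        if width <= 0:
            continue
        v_new, _ = shrink_sample(points[i], u, lam_range, checker, rng, 1e-8 * width)
        if v_new is not None:
            points[i] = v_new
    return points


def initialize_chains(
    fluxspace: FluxSpace,
    options: SamplerOptions,
    rng: np.random.Generator | None = None,
) -> ChainState:
    """Over-dispersed loopless starting sets for K chains.

    Each chain receives ``k`` loopless points generated from distinct random
    LP objectives (vertices of the polytope, cycle-stripped), then random
    chord moves until the within-chain differences span ``min(k-1, d)``
    dimensions — the spanning condition under which the sampler targets the
    uniform distribution. If ``k < d + 1`` the set can only span
    conditionally; this is accepted with a warning recorded in the state.
    """
    ss = np.random.SeedSequence(options.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(options.K + 1)]
    init_rng = rng if rng is not None else streams[-1]
    chain_streams = streams[: options.K]

    d = fluxspace.dim
    k = options.resolved_k(d)
    n = fluxspace.model.n_reactions
    checker = fluxspace.make_checker()
    warnings = []
    if k < d + 1:
        warnings.append(
            f"k={k} < d+1={d + 1}: the current set spans the space only "
            "conditionally; convergence to the uniform target is not guaranteed"
        )
    need_rank = min(k - 1, d)
    V = np.empty((options.K, k, n))
    for chain in range(options.K):
        pts = np.empty((k, n))
        for i in range(k):
            pts[i] = find_loopless_point(
                fluxspace.model, checker, init_rng, fluxspace.tol_zero,
                N_perp=fluxspace.N_perp,
            )
        pts = _diversify(pts, fluxspace, checker, init_rng, need_rank, 200 * k)
        rank = _span_rank(pts)
        if rank < need_rank:
            raise InitializationError(
                f"chain {chain}: spanning rank {rank} < required {need_rank} "
                "after diversification"
            )
        V[chain] = pts
    return ChainState(V=V, t=0, rng_streams=chain_streams, warnings=warnings)


@dataclass
class _Counters:
    accepted: int = 0
    skipped_degenerate: int = 0
    shrink_failures: int = 0
    shrinks: int = 0


def adsb_step(
    chain: np.ndarray,
    fluxspace: FluxSpace,
    loop_test,
    options: SamplerOptions,
    rng: np.random.Generator,
    counters: _Counters | None = None,
) -> int:
    """One ADSB update of a chain's point set, in place.

    Returns the index of the slot the step targeted (v_c's slot), whether or
    not the proposal was accepted — the caller stores that slot's point.
    """
    if counters is None:
        counters = _Counters()
    k = chain.shape[0]
    c, i1, i2 = rng.choice(k, size=3, replace=False)
    u = chain[i1] - chain[i2]
    norm = np.linalg.norm(u)
    if norm <= _DEGENERATE_DIRECTION:
        counters.skipped_degenerate += 1
        return int(c)
    # project the direction onto null(S): a difference of two mass-balanced
    # points already lies there up to round-off, but dividing by a small
    # ||v1 - v2|| amplifies that round-off multiplicatively over many steps,
    # so the residual must be removed before normalization
    u = fluxspace.N_perp @ (fluxspace.N_perp.T @ u)
    norm = np.linalg.norm(u)
    if norm <= _DEGENERATE_DIRECTION:
        counters.skipped_degenerate += 1
        return int(c)
    u /= norm
    lam_range = chord_limits(
        chain[c], u, fluxspace.model.lb, fluxspace.model.ub, tol=fluxspace.tol_eq * 1e3
    )
    width = lam_range[1] - lam_range[0]
    if width <= 0:
        counters.skipped_degenerate += 1
        return int(c)
    v_star, n_shrinks = shrink_sample(
        chain[c], u, lam_range, loop_test, rng, options.eps_shrink * width
    )
    counters.shrinks += n_shrinks
    if v_star is None:
        counters.shrink_failures += 1
        return int(c)
    chain[c] = v_star
    counters.accepted += 1
    return int(c)


def _reproject(points: np.ndarray, fs: FluxSpace, loop_test) -> None:
    """Cancel floating-point drift off the affine subspace, in place.

    The mass-balance constraint is homogeneous, so the projection is the
    plain orthogonal projection onto ``span(N_perp) = null(S)``. Points are
    then clipped into bounds and loop-audited; a point whose verdict flips
    under projection (possible only at the tolerance boundary) is left
    unprojected.
    """
    for i in range(points.shape[0]):
        proj = fs.N_perp @ (fs.N_perp.T @ points[i])
        np.clip(proj, fs.model.lb, fs.model.ub, out=proj)
        if not loop_test(proj):
            points[i] = proj


def _chain_counts(n_samples: int, K: int) -> list[int]:
    base = n_samples // K
    counts = [base] * K
    for i in range(n_samples - base * K):
        counts[i] += 1
    return counts


def _audit(archive: SampleArchive, fs: FluxSpace) -> dict:
    """Post-hoc feasibility audit of every archived row (bug trap)."""
    S, lb, ub = fs.model.S, fs.model.lb, fs.model.ub
    X = archive.samples
    balance = float(np.max(np.abs(X @ S.T))) if S.shape[0] else 0.0
    bound_viol = float(
        max(np.max(np.maximum(lb - X, 0.0)), np.max(np.maximum(X - ub, 0.0)))
    )
    checker = fs.make_checker()
    n_loopy = int(sum(checker(row) for row in X))
    ok = (
        balance <= fs.tol_eq
        and bound_viol <= fs.tol_eq
        and (n_loopy == 0 or archive.meta.get("sampler") == "hr")
    )
    if not ok:
        raise StateCorruptionError(
            f"archive audit failed: max |S.v|={balance:.3g}, "
            f"bound violation={bound_viol:.3g}, loop-active rows={n_loopy}"
        )
    return {
        "max_balance_residual": balance,
        "max_bound_violation": bound_viol,
        "loop_active_rows": n_loopy,
    }


def _run_population_chain(
    pts: np.ndarray,
    fs: FluxSpace,
    options: SamplerOptions,
    rng: np.random.Generator,
    n_store: int,
    direction: str,
) -> tuple[np.ndarray, _Counters]:
    """Shared driver for ADSB and ll-ACHRB (they differ only in direction).

    Stores one point every ``options.thinning`` attempted steps (skipped
    steps count toward thinning so wall-clock behavior stays predictable).
    """
    checker = fs.make_checker()
    counters = _Counters()
    stored = np.empty((n_store, pts.shape[1]))
    t = 0
    k = pts.shape[0]
    for s in range(n_store):
        last_slot = 0
        for _ in range(options.thinning):
            t += 1
            if direction == "adsb":
                last_slot = adsb_step(pts, fs, checker, options, rng, counters)
            else:  # ll-ACHRB: direction through the running center of the set
                c = int(rng.integers(k))
                r = int(rng.integers(k))
                u = pts[r] - pts.mean(axis=0)
                u = fs.N_perp @ (fs.N_perp.T @ u)  # drift control, as in ADSB
                norm = np.linalg.norm(u)
                last_slot = c
                if norm <= _DEGENERATE_DIRECTION:
                    counters.skipped_degenerate += 1
                else:
                    u /= norm
                    lam_range = chord_limits(pts[c], u, fs.model.lb, fs.model.ub)
                    width = lam_range[1] - lam_range[0]
                    if width <= 0:
                        counters.skipped_degenerate += 1
                    else:
                        v_star, ns = shrink_sample(
                            pts[c], u, lam_range, checker, rng,
                            options.eps_shrink * width,
                        )
                        counters.shrinks += ns
                        if v_star is None:
                            counters.shrink_failures += 1
                        else:
                            pts[c] = v_star
                            counters.accepted += 1
            if t % options.reproject_every == 0:
                _reproject(pts, fs, checker)
        # re-project the stored point so archived rows sit on the affine
        # subspace to SVD accuracy regardless of in-chain drift
        _reproject(pts[last_slot : last_slot + 1], fs, checker)
        stored[s] = pts[last_slot]
    return stored, counters


def _run_archive(
    fluxspace: FluxSpace, options: SamplerOptions, sampler: str
) -> SampleArchive:
    t0 = time.perf_counter()
    state = initialize_chains(fluxspace, options)
    counts = _chain_counts(options.n_samples, options.K)
    n_store = [options.burn_in + c for c in counts]

    def one_chain(j):
        return _run_population_chain(
            state.V[j].copy(), fluxspace, options, state.rng_streams[j],
            n_store[j], sampler,
        )

    if options.n_workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=options.n_workers)(
            delayed(one_chain)(j) for j in range(options.K)
        )
    else:
        results = [one_chain(j) for j in range(options.K)]

    samples = np.vstack([r[0][options.burn_in:] for r in results])
    chain_index = np.concatenate(
        [np.full(counts[j], j, dtype=int) for j in range(options.K)]
    )
    totals = _Counters()
    for _, cnt in results:
        totals.accepted += cnt.accepted
        totals.skipped_degenerate += cnt.skipped_degenerate
        totals.shrink_failures += cnt.shrink_failures
        totals.shrinks += cnt.shrinks
    meta = {
        "sampler": sampler,
        "wall_time_s": time.perf_counter() - t0,
        "counters": asdict(totals),
        "tol_eq": fluxspace.tol_eq,
        "tol_zero": fluxspace.tol_zero,
        "dim": fluxspace.dim,
        "n_loops": fluxspace.n_loops,
        "k": options.resolved_k(fluxspace.dim),
        "index_map": None
        if fluxspace.index_map is None
        else fluxspace.index_map.tolist(),
        "warnings": state.warnings,
    }
    if sampler == "ll_achrb":
        meta["non_markovian"] = True
    archive = SampleArchive(
        samples=samples,
        chain_index=chain_index,
        rxn_ids=list(fluxspace.model.rxn_ids),
        options=options,
        meta=meta,
    )
    meta["audit"] = _audit(archive, fluxspace)
    meta["wall_time_s"] = time.perf_counter() - t0
    return archive


def run_adsb(fluxspace: FluxSpace, options: SamplerOptions) -> SampleArchive:
    """ADSB sampling of the loopless space. Deterministic given the seed."""
    return _run_archive(fluxspace, options, "adsb")


def run_ll_achrb(fluxspace: FluxSpace, options: SamplerOptions) -> SampleArchive:
    """ll-ACHRB comparator: artificial-centering directions, same shrink engine."""
    return _run_archive(fluxspace, options, "ll_achrb")


def run_hr(fluxspace: FluxSpace, options: SamplerOptions) -> SampleArchive:
    """Hit-and-Run over the convex polytope (loop law ignored while moving).

    With ``options.loopless_filter`` the loop test marks each stored sample
    (column ``loop_active`` in the metadata audit); samples are never removed,
    mirroring the sample-then-verify comparison protocol.
    """
    t0 = time.perf_counter()
    fs = fluxspace
    ss = np.random.SeedSequence(options.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(options.K + 1)]
    checker = fs.make_checker()
    counts = _chain_counts(options.n_samples, options.K)
    d = fs.dim
    lb, ub = fs.model.lb, fs.model.ub

    all_chains = []
    for j in range(options.K):
        rng = streams[j]
        v = find_loopless_point(
            fs.model, checker, streams[-1], fs.tol_zero, N_perp=fs.N_perp
        )
        n_store = options.burn_in + counts[j]
        stored = np.empty((n_store, fs.model.n_reactions))
        t = 0
        for s in range(n_store):
            for _ in range(options.thinning):
                t += 1
                z = rng.standard_normal(d)
                u = fs.N_perp @ z
                norm = np.linalg.norm(u)
                if norm <= _DEGENERATE_DIRECTION:
                    continue
                u /= norm
                lam_min, lam_max = chord_limits(v, u, lb, ub)
                if lam_max - lam_min <= 0:
                    continue
                v = v + rng.uniform(lam_min, lam_max) * u
                if t % options.reproject_every == 0:
                    v = np.clip(fs.N_perp @ (fs.N_perp.T @ v), lb, ub)
            stored[s] = np.clip(fs.N_perp @ (fs.N_perp.T @ v), lb, ub)
        all_chains.append(stored[options.burn_in:])

    samples = np.vstack(all_chains)
    chain_index = np.concatenate(
        [np.full(counts[j], j, dtype=int) for j in range(options.K)]
    )
    meta = {
        "sampler": "hr",
        "wall_time_s": time.perf_counter() - t0,
        "counters": asdict(_Counters(accepted=int(np.sum(counts)) * options.thinning)),
        "tol_eq": fs.tol_eq,
        "tol_zero": fs.tol_zero,
        "dim": d,
        "n_loops": fs.n_loops,
        "k": 1,
        "index_map": None if fs.index_map is None else fs.index_map.tolist(),
        "warnings": [],
    }
    archive = SampleArchive(
        samples=samples,
        chain_index=chain_index,
        rxn_ids=list(fs.model.rxn_ids),
        options=options,
        meta=meta,
    )
    if options.loopless_filter:
        flags = np.array([checker(row) for row in samples], dtype=bool)
        meta["loop_active_fraction"] = float(flags.mean())
        archive.meta["loop_flags"] = flags
    meta["audit"] = _audit(archive, fs)
    meta["wall_time_s"] = time.perf_counter() - t0
    return archive
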