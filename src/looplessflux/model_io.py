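"""Metabolic model containers, readers/writers, and synthetic fixture networks.

A :class:`MetabolicModel` is a plain array view of a constraint-based model:
the stoichiometric matrix ``S`` (metabolites x reactions), flux bounds
``lb``/``ub`` and a boolean ``internal_mask`` separating internal conversions
(subject to the loop law) from boundary exchanges. SBML Level 3 and COBRA JSON
files are read through :mod:`cobra`; fixture networks are emitted as COBRA
JSON so every downstream tool accepts them.

The synthetic generator :func:`make_toy_network` builds a linear
substrate-to-product backbone and closes a controllable number of internal
cycles over it, so the dimension of ``null(S_int)`` — the number of type-III
(loop-law violating) pathways — equals the requested cycle count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, InvalidModelError

__all__ = [
    "MetabolicModel",
    "ToyNetworkSpec",
    "DEFAULT_BOUND",
    "load_model",
    "save_cobra_json",
    "classify_reactions",
    "make_toy_network",
    "make_box_model",
]

#: Bound substituted for reactions whose file entry omits one (COBRA convention).
DEFAULT_BOUND = 1000.0


@dataclass
class MetabolicModel:
    """Array form of a constraint-based metabolic model.

    Parameters
    ----------
    S
        Stoichiometric matrix, shape ``(m, n)`` for ``m`` balanced metabolites
        and ``n`` reactions. Coefficients are dimensionless.
    lb, ub
        Per-reaction flux bounds (mmol/gDW/h semantics; any consistent unit).
    rxn_ids, met_ids
        Reaction and metabolite identifiers, in column/row order.
    internal_mask
        ``True`` for internal reactions (participate in the loop law),
        ``False`` for exchanges crossing the system boundary.
    objective
        Optional linear objective coefficients; used only to generate seed
        points, never during sampling.
    """

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    rxn_ids: list[str]
    met_ids: list[str]
    internal_mask: np.ndarray
    objective: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.internal_mask = np.asarray(self.internal_mask, dtype=bool)
        m, n = self.S.shape
        if not (len(self.lb) == len(self.ub) == len(self.rxn_ids) == n):
            raise InvalidModelError(
                f"inconsistent reaction dimension: S has {n} columns, "
                f"lb/ub/ids have {len(self.lb)}/{len(self.ub)}/{len(self.rxn_ids)}"
            )
        if len(self.met_ids) != m:
            raise InvalidModelError(
                f"S has {m} rows but {len(self.met_ids)} metabolite ids"
            )
        if len(self.internal_mask) != n:
            raise InvalidModelError("internal_mask must cover every reaction")
        if np.any(self.lb > self.ub):
            bad = [self.rxn_ids[i] for i in np.where(self.lb > self.ub)[0]]
            raise InvalidModelError(f"lb > ub for reactions {bad}")

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def S_int(self) -> np.ndarray:
        """Stoichiometry restricted to internal reaction columns."""
        return self.S[:, self.internal_mask]

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            rxn_ids=list(self.rxn_ids),
            met_ids=list(self.met_ids),
            internal_mask=self.internal_mask.copy(),
            objective=None if self.objective is None else self.objective.copy(),
        )


@dataclass
class ToyNetworkSpec:
    """Recipe for a synthetic fixture network.

    The network is a linear pathway (one uptake exchange, ``backbone``
    internal conversions, one secretion exchange) plus ``n_cycles`` internal
    cycles, each closed by one extra chord reaction over an edge-disjoint
    backbone segment. ``cycle_lengths[i] >= 2``: a 2-cycle is a reversible
    reaction pair, a 3-cycle the canonical triangle. ``extra_exchanges``
    secretion reactions on intermediate metabolites raise the dimension of the
    flux polytope without introducing any internal cycle.
    """

    n_cycles: int = 0
    cycle_lengths: list[int] = field(default_factory=list)
    backbone: int = 3
    bound_scale: float = 1.0
    seed: int = 0
    extra_exchanges: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if not self.cycle_lengths:
            self.cycle_lengths = [3] * self.n_cycles
        if len(self.cycle_lengths) != self.n_cycles:
            raise ValueError("cycle_lengths must have n_cycles entries")
        if any(length < 2 for length in self.cycle_lengths):
            raise ValueError("every cycle length must be >= 2")
        if self.bound_scale <= 0:
            raise ValueError("bound_scale must be positive")
        needed = sum(length - 1 for length in self.cycle_lengths)
        if self.backbone < max(1, needed):
            raise ValueError(
                f"backbone of {self.backbone} internal steps cannot host "
                f"cycles of lengths {self.cycle_lengths} (needs >= {needed})"
            )


def classify_reactions(model: MetabolicModel) -> np.ndarray:
    """Classify reactions as internal (``True``) or exchange (``False``).

    The rule is purely structural: a reaction is an exchange iff its
    stoichiometric column has nonzero entries of only one sign, i.e. it is a
    pure source or pure sink across the system boundary. The verdict is
    invariant to positive rescaling of the column. No reliance on "EX_" id
    prefixes.
    """
    mask = np.empty(model.n_reactions, dtype=bool)
    for j in range(model.n_reactions):
        col = model.S[:, j]
        nz = col[col != 0.0]
        if nz.size == 0:
            raise InvalidModelError(
                f"reaction {model.rxn_ids[j]!r} touches no metabolite "
                "(all-zero stoichiometric column)"
            )
        mask[j] = bool(np.any(nz > 0) and np.any(nz < 0))
    return mask


def _from_cobra(cb_model) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    if len(cb_model.reactions) == 0:
        raise InvalidModelError(f"model {cb_model.id!r} has zero reactions")
    S = create_stoichiometric_matrix(cb_model, array_type="dense")
    lb = np.array([r.lower_bound for r in cb_model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cb_model.reactions], dtype=float)
    # missing bounds come back as None or +-inf from some writers
    lb = np.where(np.isfinite(lb), lb, -DEFAULT_BOUND)
    ub = np.where(np.isfinite(ub), ub, DEFAULT_BOUND)
    rxn_ids = [r.id for r in cb_model.reactions]
    met_ids = [m.id for m in cb_model.metabolites]
    obj = np.array([r.objective_coefficient for r in cb_model.reactions], dtype=float)
    model = MetabolicModel(
        S=S,
        lb=lb,
        ub=ub,
        rxn_ids=rxn_ids,
        met_ids=met_ids,
        internal_mask=np.ones(len(rxn_ids), dtype=bool),
        objective=obj if np.any(obj != 0) else None,
    )
    model.internal_mask = classify_reactions(model)
    return model


def load_model(path: str, format: str = "cobra_json") -> MetabolicModel:
    """Read a model from SBML Level 3 (``format='sbml'``) or COBRA JSON.

    Reactions lacking a bound receive the +-1000 COBRA default. The internal
    vs exchange partition is recomputed structurally (:func:`classify_reactions`).
    """
    import cobra.io

    if format not in ("sbml", "cobra_json"):
        raise ValueError(f"unknown model format {format!r}")
    try:
        if format == "sbml":
            cb = cobra.io.read_sbml_model(str(path))
        else:
            cb = cobra.io.load_json_model(str(path))
    except FileNotFoundError:
        raise
    except InvalidModelError:
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc
    return _from_cobra(cb)


def save_cobra_json(model: MetabolicModel, path: str) -> None:
    """Write the model as COBRA JSON (exact round-trip of S, lb, ub, ids)."""
    import cobra
    import cobra.io

    cb = cobra.Model("looplessflux_model")
    mets = [cobra.Metabolite(mid, compartment="c") for mid in model.met_ids]
    cb.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(model.rxn_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        rxns.append(rxn)
    cb.add_reactions(rxns)
    for j, rxn in enumerate(rxns):
        coeffs = {
            mets[i]: float(model.S[i, j])
            for i in range(model.n_metabolites)
            if model.S[i, j] != 0.0
        }
        rxn.add_metabolites(coeffs)
    cobra.io.save_json_model(cb, str(path))


def make_toy_network(spec: ToyNetworkSpec) -> MetabolicModel:
    """Build a synthetic network with exactly ``spec.n_cycles`` internal cycles.

    Layout: metabolites ``M1..M{B+1}``; uptake exchange ``SRC`` producing
    ``M1``; internal conversions ``M_i -> M_{i+1}``; secretion exchange
    ``SNK`` consuming the last metabolite. Cycle ``c`` of length ``l`` closes
    a chord ``M_{s+l-1} -> M_s`` (reversible) over ``l-1`` consecutive
    backbone edges; chords are placed on edge-disjoint segments so each adds
    exactly one independent vector to ``null(S_int)``. Bounds are
    heterogeneous, drawn deterministically from ``spec.seed`` and scaled by
    ``spec.bound_scale``.
    """
    rng = np.random.default_rng(spec.seed)
    n_met = spec.backbone + 1
    met_ids = [f"M{i + 1}" for i in range(n_met)]

    cols: list[np.ndarray] = []
    rxn_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    internal: list[bool] = []

    def add(rid, coeffs, lo, hi, is_internal):
        col = np.zeros(n_met)
        for i, c in coeffs.items():
            col[i] = c
        cols.append(col)
        rxn_ids.append(rid)
        lbs.append(lo)
        ubs.append(hi)
        internal.append(is_internal)

    def cap() -> float:
        return float(spec.bound_scale * rng.uniform(5.0, 15.0))

    add("SRC", {0: 1.0}, 0.0, cap(), False)
    for i in range(spec.backbone):
        add(f"B{i + 1}", {i: -1.0, i + 1: 1.0}, 0.0, cap(), True)
    add("SNK", {n_met - 1: -1.0}, 0.0, cap(), False)

    start = 0  # 0-based index of the segment's first metabolite
    for c, length in enumerate(spec.cycle_lengths):
        end = start + length - 1
        hi = cap()
        add(f"L{c + 1}", {end: -1.0, start: 1.0}, -hi, hi, True)
        start = end  # next chord reuses no backbone edge

    for e in range(spec.extra_exchanges):
        met = 1 + e % max(1, n_met - 2)  # intermediate metabolites
        add(f"EXTRA{e + 1}", {met: -1.0}, 0.0, cap(), False)

    model = MetabolicModel(
        S=np.column_stack(cols),
        lb=np.array(lbs),
        ub=np.array(ubs),
        rxn_ids=rxn_ids,
        met_ids=met_ids,
        internal_mask=np.array(internal),
    )
    # structural classification must agree with the construction
    assert np.array_equal(classify_reactions(model), model.internal_mask)
    return model


def make_box_model(lb: np.ndarray, ub: np.ndarray) -> MetabolicModel:
    """A stoichiometry-free box: n free fluxes, no metabolites, no loop law.

    Useful as a closed-form test target — the uniform distribution on the box
    has per-coordinate mean ``(lb+ub)/2`` and variance ``(ub-lb)^2/12``. All
    reactions are marked as exchanges by construction (there is no structure
    to classify).
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = len(lb)
    return MetabolicModel(
        S=np.zeros((0, n)),
        lb=lb,
        ub=ub,
        rxn_ids=[f"x{j + 1}" for j in range(n)],
        met_ids=[],
        internal_mask=np.zeros(n, dtype=bool),
    )
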