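"""Exception hierarchy shared across the toolbox.

Each error class maps to a distinct CLI exit code (see :mod:`looplessflux.cli`)
so that scripted pipelines can distinguish user errors (bad files, infeasible
models) from solver trouble and internal bugs.
"""


class LooplessFluxError(Exception):
    """Base class for all package errors."""


class FormatError(LooplessFluxError):
    """A model file could not be parsed under the declared standard."""


class InvalidModelError(LooplessFluxError):
    """The model is structurally unusable (zero reactions, empty columns...)."""


class InfeasibleModelError(LooplessFluxError):
    """The flux polytope S.v = 0, lb <= v <= ub is empty."""


class DegenerateSpaceError(LooplessFluxError):
    """The loopless space contains only the zero vector (nothing to sample)."""


class EmptySpaceError(DegenerateSpaceError):
    """Every reaction is blocked; the reduced model has no reactions."""


class SolverError(LooplessFluxError):
    """The LP backend failed; never silently interpreted as a verdict."""


class InitializationError(LooplessFluxError):
    """Chain initialization could not reach the required spanning rank."""


class AlignmentError(LooplessFluxError):
    """Two archives do not share the same reaction set/ordering."""


class StateCorruptionError(LooplessFluxError):
    """A sampler state violated an invariant it must maintain (bug trap)."""
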