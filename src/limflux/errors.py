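"""Exception hierarchy for limflux."""


class LimfluxError(Exception):
    """Base class for all limflux errors."""


class FormatError(LimfluxError, ValueError):
    """A document or expression could not be parsed."""


class ModelIntegrityError(LimfluxError, ValueError):
    """A model violates a structural invariant (e.g. undeclared species)."""


class InfeasibleProblemError(LimfluxError, RuntimeError):
    """The constraint set {x : Ex = f, Gx >= h} is empty.

    ``conflict_hint`` lists the constraint rows with the largest residual at
    the least-infeasible point, as a starting point for diagnosing which
    constraints are in conflict.
    """

    def __init__(self, message, conflict_hint=None):
        super().__init__(message)
        self.conflict_hint = conflict_hint or []


class UnboundedProblemError(LimfluxError, RuntimeError):
    """The LP objective is unbounded; ``ray_reaction`` names a flux that can
    grow without bound along an improving ray."""

    def __init__(self, message, ray_reaction=None):
        super().__init__(message)
        self.ray_reaction = ray_reaction


class DiagnosticsError(LimfluxError, RuntimeError):
    """An MCMC chain failed a basic health check (e.g. zero acceptance)."""
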