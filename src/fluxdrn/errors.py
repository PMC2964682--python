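"""Exception hierarchy shared across the package."""


class FluxdrnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FluxdrnError):
    """An input file violates its declared dialect (duplicate ids, bad columns...)."""


class ValidationError(FluxdrnError):
    """An in-memory object violates an invariant (lb > ub, unknown id...)."""


class UndefinedStatisticError(FluxdrnError):
    """A ratio statistic has an empty denominator; the value is undefined, not 0."""


class SolverError(FluxdrnError):
    """An LP did not reach an optimal solution (infeasible / unbounded)."""
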