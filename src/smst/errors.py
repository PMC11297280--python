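"""Exception hierarchy shared across the package."""


class SmstError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SmstError):
    """A file does not conform to its declared dialect."""


class DuplicateTokenError(FormatError):
    """The same token occurs more than once in an embedding file."""


class ValidationError(SmstError):
    """An object violates one of its invariants."""


class LookupError_(SmstError, KeyError):
    """A token has no embedding vector."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class DimensionError(SmstError):
    """Vector lengths disagree."""


class UndefinedSimilarityError(SmstError):
    """Cosine similarity is undefined (zero-norm vector)."""


class InfeasibilityError(SmstError):
    """A requested construction cannot be satisfied by the available pool."""


class DesignError(SmstError):
    """An experiment design parameterization is internally inconsistent."""


class SchedulingError(SmstError):
    """A trial ordering constraint could not be satisfied."""


class ConvergenceError(SmstError):
    """A model fit failed to converge (e.g. perfect separation)."""


class PipelineError(SmstError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
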