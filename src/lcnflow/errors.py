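"""Exception hierarchy for lcnflow."""


class LcnflowError(Exception):
    """Base class for all lcnflow errors."""


class ValidationError(LcnflowError, ValueError):
    """Domain-object invariant violated (bad kind, negative length, ...)."""


class SchemaError(LcnflowError, ValueError):
    """A file is missing required columns or attributes."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class StructuralError(LcnflowError, ValueError):
    """Network topology is inconsistent (dangling endpoint, duplicate id)."""


class SingularNetworkError(LcnflowError, RuntimeError):
    """A connected component has no boundary node: the flow problem is singular."""


class SolverError(LcnflowError, RuntimeError):
    """The linear solve produced non-finite values or a large residual."""
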