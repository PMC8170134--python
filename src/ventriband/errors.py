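"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class MeshingError(RuntimeError):
    """Raised when a contour stack cannot be turned into a valid mesh."""


class ParseError(ValueError):
    """Raised when a geometry/material file cannot be parsed."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative procedure fails to converge.

    Carries the iterate ``history`` (list of per-iteration records) for
    diagnostics.
    """

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history if history is not None else []
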