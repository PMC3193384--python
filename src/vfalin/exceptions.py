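"""Package-specific error types."""


class InsufficientDataError(ValueError):
    """Too few (distinct) measurements to determine the requested fit."""


class DegenerateFitError(RuntimeError):
    """The fit exists but implies non-physical parameters (e.g. slope >= 0)."""


class ConvergenceError(RuntimeError):
    """An iterative procedure failed to converge within its budget."""
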