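"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class FitFailureError(RuntimeError):
    """A stock-recruitment fit did not converge.

    Carries the per-restart diagnostics so callers can log or inspect them.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NoSolutionError(RuntimeError):
    """A well-posed request has no solution (e.g. all-immature stock)."""
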