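"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input violates a documented precondition of an operation."""


class FitConvergenceError(RuntimeError):
    """A model fit failed to converge; the message carries diagnostics."""
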