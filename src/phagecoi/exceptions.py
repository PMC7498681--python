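"""Exception hierarchy for phagecoi."""


class PhagecoiError(Exception):
    """Base class for all phagecoi errors."""


class DomainError(PhagecoiError, ValueError):
    """An input violates the mathematical domain of an operation."""


class UsageError(PhagecoiError, ValueError):
    """An argument is structurally invalid (unknown name, bad shape, bad edges)."""


class FitError(PhagecoiError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
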