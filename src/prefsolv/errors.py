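"""Exception hierarchy shared across the package."""


class PrefsolvError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PrefsolvError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InputError(PrefsolvError, ValueError):
    """Malformed, insufficient, or inconsistent input data."""


class ParseError(InputError):
    """A delimited text file could not be parsed; carries a line number where possible."""


class DegenerateEndpointsError(DomainError):
    """Pure-solvent transition energies coincide; shell composition is unidentifiable."""


class SingularDesignError(InputError):
    """The regression design matrix is rank-deficient."""

    def __init__(self, message: str, collinear_columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.collinear_columns = collinear_columns


class WrongVariantError(DomainError):
    """An operation specific to one model variant was called with the other."""


class NonConvergenceError(PrefsolvError, RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, start_log: list | None = None):
        super().__init__(message)
        self.start_log = start_log or []
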