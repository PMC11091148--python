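"""Exception hierarchy shared across the package."""


class EcgCancelError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EcgCancelError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(EcgCancelError, ValueError):
    """An input is structurally valid but statistically degenerate
    (zero power, zero variance, constant signal)."""


class FormatError(EcgCancelError, ValueError):
    """A file could not be parsed; the message names the offending
    location."""


class NumericalError(EcgCancelError, ArithmeticError):
    """A linear-algebra step failed (e.g. singular normal equations)."""


class RevocationError(EcgCancelError):
    """Re-keying did not produce a fresh template."""


class SubjectNotFoundError(EcgCancelError, KeyError):
    """No enrollment record exists for the requested subject."""
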