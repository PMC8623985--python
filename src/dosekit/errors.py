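"""Exception hierarchy for dosekit.

All validation failures raise subclasses of :class:`DosekitError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class DosekitError(Exception):
    """Base class for all dosekit errors."""


class FormatError(DosekitError):
    """A delimited-text input does not have the expected layout."""


class ValidationError(DosekitError):
    """Input parsed, but violates a domain invariant."""


class UndefinedRatioError(DosekitError):
    """A requested ratio has a zero (or all-zero) denominator."""


class FitError(DosekitError):
    """A time-activity curve cannot be fitted from the available points."""


class UnitError(DosekitError):
    """Quantities with incompatible units were combined."""
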