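"""Exception hierarchy.

Contract violations (caller bugs) raise :class:`ContractError`; malformed
inputs raise a :class:`FormatError` subclass; data that parse but fail the
study's quality gates (trial too short, no valid samples, hand out of view)
raise :class:`QualityError` so callers can distinguish "fix your code" from
"exclude this trial".
"""


class TapMocapError(Exception):
    """Base class for all package errors."""


class ContractError(TapMocapError, ValueError):
    """A precondition of an operation was violated by the caller."""


class FormatError(TapMocapError, ValueError):
    """A file did not conform to the expected on-disk dialect."""


class SchemaError(FormatError):
    """A tabular file is missing required columns or ordering."""


class CalibrationError(FormatError):
    """Camera parameters are inconsistent or non-physical."""


class QualityError(TapMocapError):
    """Data parsed correctly but fail a trial-quality gate."""


class GenerationError(TapMocapError):
    """A synthetic scene could not be rendered under its constraints."""
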