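"""Exception hierarchy for data validation and analysis failures.

Validation problems raise a distinct, named subclass of
:class:`ValidationError` so callers can react to (or test for) each
failure mode individually.
"""


class MailedFITError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MailedFITError):
    """A record or input table violates the data contract."""


class MissingColumnError(ValidationError):
    """The input table lacks one or more required columns."""


class NonNumericCountError(ValidationError):
    """A count column (clinics, kits, screened) is not a valid integer."""


class ScreenedExceedsMailedError(ValidationError):
    """A record reports more completed screenings than kits mailed."""


class UnknownAdaptationCodeError(ValidationError):
    """An adaptation code is not one of M, Ph, S, I, E."""


class DuplicateRecordError(ValidationError):
    """Two rows share the same (system_id, program_year) key."""


class UndefinedRateError(MailedFITError):
    """Completion rate requested for a record with zero kits mailed."""


class DegenerateCalibrationError(MailedFITError):
    """Tertile calibration impossible (too few or constant values)."""


class CodingError(MailedFITError):
    """A record's field value falls outside every level of a factor."""


class SchemaError(MailedFITError):
    """A configuration references a factor absent from the table schema."""


class SingularDesignError(MailedFITError):
    """Regression design matrix is singular (e.g. constant covariate)."""
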