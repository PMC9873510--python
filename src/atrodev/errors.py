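"""Exception hierarchy for the atrophy-deviation pipeline.

Every error raised deliberately by the package derives from
:class:`AtrodevError`, so callers can catch pipeline failures without
swallowing programming errors.
"""


class AtrodevError(Exception):
    """Base class for all errors raised by atrodev."""


class FormatError(AtrodevError):
    """A file does not have the expected overall layout (e.g. missing header)."""


class ParseError(AtrodevError):
    """A cell or field could not be parsed; the message names the location."""


class ValidationError(AtrodevError):
    """Parsed data violates a domain invariant (duplicate ids, negative age, ...)."""


class ReconciliationError(AtrodevError):
    """Two input sources disagree on which scans exist; message lists the ids."""


class ConfigurationError(AtrodevError):
    """An analysis or simulation option is invalid or refers to missing data."""


class DegenerateDesignError(AtrodevError):
    """A baseline fit is impossible: all pre-event ages identical."""


class EligibilityViolationError(AtrodevError):
    """A fit was requested on a series that does not meet the inclusion rules."""


class DegenerateStandardizationError(AtrodevError):
    """Residual SD is zero while some raw residual is not: z is undefined."""


class VariantError(AtrodevError):
    """The requested test variant is undefined for the given sample sizes."""


class NoPostDataError(AtrodevError):
    """A region test was requested with no post-event residuals at all."""
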