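"""Exception hierarchy.

Every error raised by the package derives from :class:`SepsistrajError`, so
callers can catch one type at pipeline level while tests discriminate on the
specific subclass.
"""


class SepsistrajError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SepsistrajError):
    """Invalid configuration (bad priors, horizon too short, bad budget...)."""


class FormatError(SepsistrajError):
    """On-disk table does not match the documented schema."""


class DataError(SepsistrajError):
    """Input data are structurally valid but semantically unusable
    (missing patient, unknown drug, absent required column)."""


class ContractViolation(SepsistrajError):
    """An API precondition was violated by the caller."""


class TrainingError(SepsistrajError):
    """Model fitting cannot proceed (e.g. a required class is absent)."""


class UndefinedMetricError(SepsistrajError):
    """A metric is undefined for the given inputs (single-class labels)."""


class CapabilityError(SepsistrajError):
    """Requested operation is not supported for this model type."""
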