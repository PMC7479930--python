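"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`AdminQCError` so callers can catch
configuration and data problems with a single except clause while letting
programming errors propagate.
"""


class AdminQCError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(AdminQCError):
    """A declared variable or role is inconsistent with the data."""


class ConfigurationError(AdminQCError):
    """A configuration entry (rule, check parameter, pattern) is invalid."""


class DataFormatError(AdminQCError):
    """The input file violates the rectangular long-format contract."""


class DataError(AdminQCError):
    """Data values violate a precondition of a check (e.g. non-binary indicator)."""


class InsufficientDataError(AdminQCError):
    """Too few non-missing values to compute the requested statistic."""
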