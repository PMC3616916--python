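"""Exception hierarchy.

Every error raised by the library derives from :class:`OrphanAuditError`,
so callers (and the CLI) can catch one type.
"""


class OrphanAuditError(Exception):
    """Base class for all orphanaudit errors."""


class ConfigurationError(OrphanAuditError):
    """An invalid configuration value; the message names the offending field."""


class ConsistencyError(OrphanAuditError):
    """Inputs that should share an identifier universe do not."""


class DegenerateInputError(OrphanAuditError):
    """Input too small or empty for the operation to be defined."""


class StatisticsError(OrphanAuditError):
    """Not enough data to compute the requested statistic."""


class UndefinedValueError(OrphanAuditError):
    """The requested quantity is undefined for this input (e.g. GC of all-N)."""


class ParseError(OrphanAuditError):
    """A malformed input row; the message carries the line number."""
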