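"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`ChromEnrichError`, so callers can catch package failures without
masking programming errors.
"""


class ChromEnrichError(Exception):
    """Base class for all chromenrich errors."""


class CoordinateError(ChromEnrichError, ValueError):
    """An interval or point lies outside its genome layout, or end <= start."""


class ConfigurationError(ChromEnrichError, ValueError):
    """Inconsistent inputs: layout mismatch, infeasible simulation config, ..."""


class ParseError(ChromEnrichError, ValueError):
    """A file could not be parsed; message carries the offending line number."""


class ValidationError(ChromEnrichError, ValueError):
    """A parsed structure violates a semantic constraint (e.g. non-monotone map)."""


class ExtrapolationError(ChromEnrichError, ValueError):
    """A queried position falls outside a genetic map's interpolation domain."""


class UndefinedRatioError(ChromEnrichError, ZeroDivisionError):
    """A proportion or ratio has a zero denominator; never reported as infinity."""


class PreconditionError(ChromEnrichError, ValueError):
    """An operation's documented precondition was violated by the caller."""
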