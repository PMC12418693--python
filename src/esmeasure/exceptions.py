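"""Exception hierarchy.

Everything derives from :class:`ESMeasureError` so callers can catch the
package's own failures without masking programming errors.
"""


class ESMeasureError(Exception):
    """Base class for all esmeasure errors."""


class FormatError(ESMeasureError):
    """A file is structurally malformed (e.g. a required column is absent)."""


class ValidationError(ESMeasureError):
    """Data violates a domain invariant (score range, duplicates, references)."""


class ConfigurationError(ESMeasureError):
    """A configuration object violates its own invariants."""


class EligibilityError(ESMeasureError):
    """A subject does not meet the preconditions of a scoring operation."""


class DomainError(ESMeasureError):
    """An operation was called outside its stated domain (e.g. ES at baseline)."""


class UndefinedCorrelationError(ESMeasureError):
    """Correlation requested on a zero-variance sample."""


class SearchFailureError(ESMeasureError):
    """The sample-size search exceeded its cap without reaching target power."""
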