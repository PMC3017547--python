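"""Exception hierarchy.

``FormatError`` maps to CLI exit code 2; everything else that reaches the CLI
surfaces as exit code 1.
"""


class ImprintArrayError(Exception):
    """Base class for all package errors."""


class FormatError(ImprintArrayError):
    """A table file violates the expected on-disk format."""


class ValidationError(ImprintArrayError):
    """In-memory data violates a domain invariant or precondition."""


class UndefinedResultError(ImprintArrayError):
    """A statistic is requested whose denominator is empty."""
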