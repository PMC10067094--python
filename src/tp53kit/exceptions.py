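"""Exception hierarchy shared across the package."""


class TP53KitError(Exception):
    """Base class for all package errors."""


class ParseError(TP53KitError, ValueError):
    """Raised when an input file or string cannot be parsed."""


class ValidationError(TP53KitError, ValueError):
    """Raised when parsed data violates a structural invariant."""
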