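"""Exception types shared across the package."""


class DNBError(Exception):
    """Base class for all package errors."""


class ValidationError(DNBError, ValueError):
    """An input object violates a documented invariant.

    The message names the violated invariant so callers can report it.
    """


class ParseError(DNBError, ValueError):
    """A file could not be parsed; the message carries row/column context."""
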