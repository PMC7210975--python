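"""Exception types shared across the package."""


class ScatlasError(Exception):
    """Base class for package errors."""


class FormatError(ScatlasError, ValueError):
    """A file could not be parsed or its pieces are mutually inconsistent."""


class ValidationError(ScatlasError, ValueError):
    """Inputs violate a documented precondition or invariant."""
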