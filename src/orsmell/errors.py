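"""Exception hierarchy shared across the package."""


class OrsmellError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OrsmellError, ValueError):
    """A file or matrix does not conform to its on-disk contract."""


class ValidationError(OrsmellError, ValueError):
    """An in-memory object violates a domain invariant."""


class FitError(OrsmellError, RuntimeError):
    """A statistical fit is undefined for the given input."""
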