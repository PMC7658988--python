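"""Exception types shared across the package."""


class ChromclustError(Exception):
    """Base class for package errors."""


class ValidationError(ChromclustError, ValueError):
    """Invalid parameter or malformed input."""


class EmptyResultError(ChromclustError, RuntimeError):
    """A filtering step removed everything."""
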