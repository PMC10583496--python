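"""Exception hierarchy shared across the package."""


class SpeechlexError(Exception):
    """Base class for package errors."""


class ValidationError(SpeechlexError, ValueError):
    """Malformed input: bad file, bad schema, bad dialect marker, bad config."""


class PreconditionError(SpeechlexError, RuntimeError):
    """A statistical precondition is violated (constant stratum, group too
    small, undefined correlation)."""
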