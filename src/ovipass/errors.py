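"""Exception types shared across the package."""


class OvipassError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OvipassError, ValueError):
    """An input violates a documented precondition or invariant."""


class ProfileParseError(ValidationError):
    """A lineage-profile file could not be parsed; the message names the offending line."""


class CapabilityError(OvipassError, RuntimeError):
    """The requested exact computation is too large; the message points to the
    Monte-Carlo route instead."""
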