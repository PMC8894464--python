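"""Exception hierarchy for ccmnet."""


class CCMNetError(Exception):
    """Base class for all ccmnet errors."""


class ValidationError(CCMNetError, ValueError):
    """Raised when an input violates an operation's precondition."""


class InvalidParameterError(CCMNetError, ValueError):
    """Raised when simulation parameters produce undefined dynamics."""
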