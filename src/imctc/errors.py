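"""Exception types shared across the package."""


class InsufficientDataError(ValueError):
    """Raised when an operation receives too few informative observations."""


class InvalidStateError(RuntimeError):
    """Raised when an object is used before it has been fitted/initialised."""
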