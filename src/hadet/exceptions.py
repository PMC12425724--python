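"""Shared exception types."""


class InvalidSpecError(ValueError):
    """A shuffle/model specification is inconsistent with its input."""


class InvalidConfigError(ValueError):
    """An attention/loss configuration is malformed."""


class DegenerateInputError(ValueError):
    """Input shape admits no well-defined result (e.g. a 1x1 energy slice)."""


class InvalidBoxError(ValueError):
    """A bounding box violates w > 0, h > 0."""


class DomainError(ValueError):
    """A scalar argument is outside the function's domain."""
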