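"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract (bad shapes,
    out-of-bounds coordinates, inconsistent configuration)."""


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; the message names
    the offending path."""
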