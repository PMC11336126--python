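"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """A precondition on an operation's arguments was violated."""


class DataQualityError(RuntimeError):
    """The data fail a quality gate (too many bad channels, no kept epochs, ...)."""


class UndefinedCorrelationError(ArithmeticError):
    """Spatial correlation requested for a zero-variance topography."""
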