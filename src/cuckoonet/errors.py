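"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A delimited-text file could not be parsed; the message names the offending line or cell."""


class UndefinedMetricError(ValueError):
    """A confusion-matrix metric has a zero denominator for these counts."""
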