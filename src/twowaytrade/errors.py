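"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A fatal input problem: missing column, empty file, invalid config."""


class UndefinedMetricError(ArithmeticError):
    """A statistic was requested on a scope where it is undefined
    (e.g. a share with a zero denominator, a percent change from zero)."""
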