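"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


class UndefinedMetricError(ValueError):
    """A metric's denominator class is empty, so the metric is undefined."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; the run was aborted."""
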