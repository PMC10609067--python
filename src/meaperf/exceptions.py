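"""Exception types shared across the pipeline stages."""


class InvalidParameterError(ValueError):
    """A parameter violates a precondition (non-positive rate, bad band edges...)."""


class DegenerateTestError(ValueError):
    """A statistical test cannot be formed (e.g. pooled proportion of 0 or 1)."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. SNR with zero noise)."""


class NormalizationError(ValueError):
    """A normalization reference (background bin, control geometric mean) is invalid."""
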