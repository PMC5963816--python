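"""Package-specific error types."""


class InvalidParameterError(ValueError):
    """A parameter is outside its physically or mathematically valid range."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class StructureMismatchError(ValueError):
    """Two datasets that must share structure (masks, keys) do not."""
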