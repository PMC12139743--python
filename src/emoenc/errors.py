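"""Shared exception types."""


class DegenerateDataError(ValueError):
    """Raised when an input has zero variance where variance is required
    (constant baselines, identical paired samples, constant ages...)."""


class SchemaError(ValueError):
    """Raised when a tabular input does not conform to its documented schema."""
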