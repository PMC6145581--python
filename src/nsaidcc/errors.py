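"""Exception hierarchy shared across the pipeline."""


class NsaidccError(Exception):
    """Base class for all package errors."""


class ConfigError(NsaidccError):
    """Invalid simulation or analysis configuration."""


class SchemaError(NsaidccError):
    """An input table is missing required columns or has bad types."""


class DataError(NsaidccError):
    """Input rows violate a data invariant (e.g. overlapping enrollment)."""


class ContractError(NsaidccError):
    """A caller violated an operation precondition."""


class EstimationError(NsaidccError):
    """Model fitting is impossible (e.g. no informative matched sets)."""


class PipelineError(NsaidccError):
    """An orchestrated analysis step received unusable upstream output."""
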