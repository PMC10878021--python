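"""Exception types shared across the pipeline stages."""


class TxPanelError(Exception):
    """Base class for all package errors."""


class PanelFormatError(TxPanelError):
    """A file does not conform to its expected tabular format."""


class ValidationError(TxPanelError):
    """An in-memory table violates a structural invariant."""


class InsufficientDataError(TxPanelError):
    """Too few complete observations to compute a statistic."""


class PipelineError(TxPanelError):
    """A pipeline stage failed; the message names the stage and cause."""
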