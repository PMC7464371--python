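"""Exception hierarchy for txmap."""


class TxmapError(Exception):
    """Base class for all txmap errors."""


class FormatError(TxmapError):
    """A file does not conform to the expected tabular format."""


class ValidationError(TxmapError):
    """Input parsed but violates a domain invariant."""


class PipelineError(TxmapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
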