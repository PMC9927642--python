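"""Exception hierarchy shared across the pipeline."""


class DfspError(Exception):
    """Base class for all package errors."""


class ValidationError(DfspError, ValueError):
    """Input violates a documented precondition or invariant."""


class PipelineError(DfspError, RuntimeError):
    """A pipeline stage failed; carries the stage name for CLI reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
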