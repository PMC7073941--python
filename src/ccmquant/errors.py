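"""Exception hierarchy shared across the pipeline."""


class CcmQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(CcmQuantError, ValueError):
    """Invalid input values, schemas or configuration."""


class CalibrationError(CcmQuantError, RuntimeError):
    """Calibration series cannot be fit or is degenerate."""


class MissingInternalStandardError(CcmQuantError, RuntimeError):
    """Internal-standard channel absent or zero; no response ratio exists."""


class PipelineStageError(CcmQuantError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
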