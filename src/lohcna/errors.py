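"""Exception hierarchy shared across the pipeline stages."""


class LohcnaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LohcnaError):
    """An invalid configuration value; the message names the offending field."""


class GenerationError(LohcnaError):
    """Synthetic cohort could not be generated as requested."""


class AlignmentError(LohcnaError):
    """Paired matrices disagree on probe or sample identifiers."""


class PairingError(LohcnaError):
    """A sample is present in one tissue but not its pair."""


class AnnotationError(LohcnaError):
    """A probe is missing from, or malformed in, the annotation table."""


class ClinicalTableError(LohcnaError):
    """A clinical row failed validation; the message carries the row number."""


class CutoffError(LohcnaError):
    """No cutoff on the grid attains the requested FDR target."""


class DegenerateDesignError(LohcnaError):
    """A Cox design matrix contains a constant (or collinear) covariate."""


class UsageError(LohcnaError):
    """An operation was invoked with incompatible arguments."""


class PipelineStageError(LohcnaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
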