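"""Exception hierarchy shared across the pipeline.

``ValidationError`` signals bad user input (CLI exit code 1); everything else
that goes wrong at run time surfaces as ``PipelineError`` (exit code 2).
"""


class ArmadielError(Exception):
    """Base class for all package errors."""


class ValidationError(ArmadielError, ValueError):
    """Invalid input data or configuration."""


class UnsupportedLocationError(ValidationError):
    """Latitude inside a polar circle, where sunrise/sunset may not exist."""


class ContractError(ArmadielError):
    """An operation was called outside its documented precondition."""


class PipelineError(ArmadielError):
    """A pipeline stage failed at run time."""


class ConvergenceError(PipelineError):
    """Model optimizer failed to converge; carries the final gradient norm."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm
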