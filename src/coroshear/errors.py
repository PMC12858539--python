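"""Exception hierarchy shared across the package."""


class CoroshearError(Exception):
    """Base class for all package errors."""


class ValidationError(CoroshearError, ValueError):
    """Invalid user input: parameters outside their admissible range."""


class GeometryError(CoroshearError):
    """Degenerate or inconsistent vessel geometry."""


class FormatError(CoroshearError):
    """Malformed or inconsistent on-disk field data."""


class SeparationError(CoroshearError):
    """Complete or quasi-complete separation in a logistic fit.

    Refit with ``firth=True`` to obtain a penalized estimate.
    """


class PipelineStageError(CoroshearError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
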