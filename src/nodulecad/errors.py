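"""Exception hierarchy shared across the package."""


class NoduleCADError(Exception):
    """Base class for all package errors."""


class ValidationError(NoduleCADError, ValueError):
    """Raised when an input or configuration violates a documented precondition."""


class PlacementError(NoduleCADError, RuntimeError):
    """Raised when phantom geometry cannot be placed without overlap."""


class NotFittedError(NoduleCADError, RuntimeError):
    """Raised when predict/transform is called on an unfitted model."""


class UndefinedMetricError(NoduleCADError, ValueError):
    """Raised when a metric is undefined for the given inputs (e.g. a class
    missing from y_true). The message names the offending metric."""


class StageError(NoduleCADError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
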