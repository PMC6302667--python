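"""Exception hierarchy shared across the pipeline."""


class FoldCVAEError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FoldCVAEError):
    """A parameter, bound, or search-space value is invalid."""


class DataError(FoldCVAEError):
    """Input arrays are malformed (shape mismatch, non-finite values)."""


class FormatError(FoldCVAEError):
    """A file on disk does not conform to the expected layout."""


class StateError(FoldCVAEError):
    """An operation was called on an object in the wrong state
    (e.g. diagnostics on an untrained model)."""


class TrainingDivergedError(FoldCVAEError):
    """The loss became non-finite during optimisation."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch}")
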