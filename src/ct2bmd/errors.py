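"""Exception hierarchy shared by all ct2bmd modules."""


class CT2BMDError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CT2BMDError):
    """Input file is unreadable or not in a supported format."""


class UnsupportedInputError(CT2BMDError):
    """Readable input that the pipeline does not handle (multi-frame, color, ...)."""


class BoundsError(CT2BMDError):
    """ROI extends outside the slice."""


class DegenerateROIError(CT2BMDError):
    """ROI mask is empty or has no co-occurring pixel pairs."""


class ParameterError(CT2BMDError):
    """Invalid parameter value (Ng < 2, unsupported angle, bad fractions, ...)."""


class DegenerateCalibrationError(CT2BMDError):
    """Fewer than two distinct phantom HU values — no line can be fit."""


class DegenerateDataError(CT2BMDError):
    """Statistic undefined on the given data (e.g. Pearson R of a constant vector)."""


class TrainingDivergedError(CT2BMDError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch}")


class SchemaError(CT2BMDError):
    """Tabular input is missing required columns or rows do not line up."""
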