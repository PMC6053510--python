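"""Exception and warning types shared across the package."""


class GaitSpeedError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GaitSpeedError):
    """A CSV row could not be parsed; carries the 1-based data-row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EmptyInputError(GaitSpeedError):
    """Fewer samples than the minimum a recording needs."""


class ConfigError(GaitSpeedError):
    """A configuration value violates a hard constraint (e.g. rate < 50 Hz)."""


class TooShortError(GaitSpeedError):
    """A series is too short for the requested filter."""


class DegenerateStepError(GaitSpeedError):
    """A step interval is too short to compute features on."""


class InsufficientCalibrationError(GaitSpeedError):
    """Not enough labeled steps, or a single unique label speed."""


class ModelCompatibilityError(GaitSpeedError):
    """A persisted model does not match the current feature contract."""


class SignalQualityWarning(UserWarning):
    """Gravity estimate outside the plausible band (device shaken / freefall)."""


class AlignmentWarning(UserWarning):
    """Horizontal principal directions too isotropic to orient reliably."""


class CalibrationWarning(UserWarning):
    """A supervised walk was excluded from the training set."""
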