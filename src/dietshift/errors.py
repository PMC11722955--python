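"""Exception hierarchy shared across the package."""


class DietShiftError(ValueError):
    """Base class for all validation and modelling errors."""


class ValidationError(DietShiftError):
    """An input object violates a domain invariant."""


class SchemaError(DietShiftError):
    """A file is missing required columns/keys or is structurally malformed."""


class CalibrationError(DietShiftError):
    """Back-solving a plant-source intensity failed."""


class DegenerateCalibrationError(CalibrationError):
    """The unknown source carries zero weight, so its intensity is unidentifiable."""


class InfeasibleCalibrationError(CalibrationError):
    """The back-solved intensity would be negative."""
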