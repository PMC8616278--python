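"""Exception hierarchy shared across the package."""


class EscmechError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EscmechError, ValueError):
    """A supplied parameter is outside its documented domain."""


class DataError(EscmechError, ValueError):
    """Input data violate a structural precondition (units, sampling, size)."""


class FormatError(EscmechError, ValueError):
    """A file does not conform to the expected dialect."""


class StateError(EscmechError, RuntimeError):
    """An operation was called in an invalid order (e.g. double trap subtraction)."""


class GeometryError(EscmechError, ValueError):
    """A mask or profile violates a geometric precondition."""


class CalibrationError(EscmechError, RuntimeError):
    """A calibration could not be established from the supplied data."""


class EstimationError(EscmechError, RuntimeError):
    """An estimator could not produce a result from the supplied data."""
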