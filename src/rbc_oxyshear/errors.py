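"""Exception hierarchy for the rbc_oxyshear package."""


class RBCOxyShearError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(RBCOxyShearError, ValueError):
    """A diffraction measurement violates its physical preconditions."""


class InsufficientDataError(RBCOxyShearError, ValueError):
    """Too few usable points remain for a fit."""


class NonPhysicalFitError(RBCOxyShearError, ValueError):
    """A fit produced parameters outside their physical domain
    (e.g. a non-positive Lineweaver-Burke intercept)."""


class GridMismatchError(RBCOxyShearError, ValueError):
    """Curves or fields that must share a grid do not."""


class FitFailureError(RBCOxyShearError, RuntimeError):
    """All restarts of a nonlinear fit failed to converge."""


class CalibrationRangeError(RBCOxyShearError, ValueError):
    """Requested value lies outside the attainable range of a calibration."""


class SolverError(RBCOxyShearError, RuntimeError):
    """The flow solver failed to converge."""


class ConfigurationError(RBCOxyShearError, ValueError):
    """A run/flow configuration is invalid (e.g. CFL violation)."""


class GeometryError(RBCOxyShearError, ValueError):
    """A geometric query cannot be answered (empty band, no wall cells...)."""


class SchemaError(RBCOxyShearError, ValueError):
    """An input file does not conform to the declared dialect."""


class UndefinedStatisticError(RBCOxyShearError, ZeroDivisionError):
    """A statistic (e.g. R^2 with zero variance) is undefined on this input."""
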