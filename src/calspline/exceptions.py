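"""Exception hierarchy for calspline."""


class CalsplineError(Exception):
    """Base class for all calspline errors."""


class DegenerateKnotsError(CalsplineError):
    """Requested knots are not strictly increasing (e.g. tied quantiles)."""


class ValidationError(CalsplineError):
    """Input data violate a structural requirement."""


class CalibrationError(CalsplineError):
    """Calibration subset is unusable (too small, contains cases, no W spread)."""


class ConvergenceError(CalsplineError):
    """Optimizer failed in a way that cannot be reported as a flagged fit."""


class SeparationError(ConvergenceError):
    """The conditional likelihood is unbounded (perfect separation)."""
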