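"""Exception hierarchy for mabsim."""


class MabsimError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MabsimError, ValueError):
    """An argument violates a documented precondition (negative dose, NaN, ...)."""


class ConfigurationError(MabsimError, ValueError):
    """A configuration file or parameter set is inconsistent or unknown."""


class NumericalError(MabsimError, RuntimeError):
    """An ODE solve or root-finding step failed to converge."""


class CalibrationError(MabsimError, RuntimeError):
    """The catabolic-clearance calibration cannot reach the reference clearance."""


class UnitError(MabsimError, ValueError):
    """An unsupported unit conversion was requested."""


class ExtrapolationError(MabsimError, RuntimeError):
    """Terminal-phase extrapolation failed (non-decaying tail)."""
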