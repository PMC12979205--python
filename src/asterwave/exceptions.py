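"""Exception hierarchy.

All package errors derive from :class:`AsterWaveError` so callers can catch
one base class; configuration/user errors and numerical failures are kept
distinct because the CLI maps them to different exit codes.
"""


class AsterWaveError(Exception):
    """Base class for all asterwave errors."""


class InvalidParameterError(AsterWaveError, ValueError):
    """A model or config parameter violates its physical constraints."""


class ConfigurationError(AsterWaveError, ValueError):
    """An inconsistent run setup (CFL violation, degenerate axis, ...)."""


class ConvergenceError(AsterWaveError, RuntimeError):
    """Steady-state iteration did not converge within the allowed time."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class NumericalBlowupError(AsterWaveError, RuntimeError):
    """NaN/overflow during time integration; carries the last valid time."""

    def __init__(self, message, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class NoInvasionError(AsterWaveError, RuntimeError):
    """No invasion occurs (stable regime or threshold never reached).

    For stable parameter sets ``decay_time`` carries the e-folding time of
    the decaying mass asymmetry instead.
    """

    def __init__(self, message, decay_time=None):
        super().__init__(message)
        self.decay_time = decay_time


class SegmentationError(AsterWaveError, RuntimeError):
    """Compartment segmentation could not find the required boundaries."""


class FitFailureError(AsterWaveError, RuntimeError):
    """All optimizer starts failed or the model cannot describe the data."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NonIdentifiableError(AsterWaveError, RuntimeError):
    """The data carry no information on the requested parameter."""


class EmptyInputError(AsterWaveError, ValueError):
    """An estimator received no usable data."""


class ParseError(AsterWaveError, ValueError):
    """A file does not conform to the documented format."""

    def __init__(self, message, line=None, column=None):
        super().__init__(message)
        self.line = line
        self.column = column
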