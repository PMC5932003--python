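"""Package-specific exceptions."""


class PeatfluxError(Exception):
    """Base class for all peatflux errors."""


class CurveFormatError(PeatfluxError):
    """A calibration-curve file could not be parsed; names the offending line."""


class CalibrationRangeError(PeatfluxError):
    """A radiocarbon date lies outside the support of the calibration curve."""


class ReversalError(PeatfluxError):
    """Too few age-depth iterations survive the stratigraphic-order constraint."""


class ConvergenceError(PeatfluxError):
    """An MCMC run stalled (no accepted move for a long stretch)."""


class ConfigError(PeatfluxError):
    """A pipeline configuration failed validation; names the offending field."""
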