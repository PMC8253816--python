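"""Exception hierarchy shared across the package."""


class CondensateError(Exception):
    """Base class for all package-specific errors."""


class UncalibratedStackError(CondensateError):
    """A stack was loaded without pixel-size / frame-interval calibration.

    Physical calibration is never defaulted silently: a missing sidecar must
    be compensated by explicit keyword arguments.
    """


class GeometryError(CondensateError, ValueError):
    """An ROI or droplet geometry violates a precondition (e.g. overlap)."""


class FitError(CondensateError, RuntimeError):
    """A least-squares fit failed, diverged, or the data are unidentifiable."""


class NormalizationError(CondensateError, ValueError):
    """A normalization step is undefined (zero/negative reference signal)."""
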