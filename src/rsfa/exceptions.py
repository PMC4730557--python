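"""Exception types shared across the package."""


class RsfaError(Exception):
    """Base class for package errors."""


class InvalidConfigError(RsfaError, ValueError):
    """A generator or analysis configuration value is out of range."""


class ShapeError(RsfaError, ValueError):
    """Array shapes or grids do not agree."""


class BandError(RsfaError, ValueError):
    """A frequency band is empty, inverted, or exceeds the Nyquist limit."""


class DesignError(RsfaError, ValueError):
    """A regression design is rank deficient or otherwise unusable."""


class InsufficientDataError(RsfaError, ValueError):
    """Too few samples, beats, or participants for the requested estimate."""


class DetectionError(RsfaError, RuntimeError):
    """Beat detection failed (flat signal or too few peaks)."""


class DegenerateSeriesError(RsfaError, ValueError):
    """An interval series collapsed (all values removed or constant)."""


class ConvergenceError(RsfaError, RuntimeError):
    """Iterative decomposition failed to converge after restarts."""
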