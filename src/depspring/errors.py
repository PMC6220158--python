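"""Exception types shared across the package."""


class DepSpringError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DepSpringError, ValueError):
    """An invalid configuration (ranges, grids, schedules, ...)."""


class GeometryError(DepSpringError, ValueError):
    """Geometrically impossible device/cell combination (e.g. R >= h)."""


class NoBalanceError(DepSpringError, ValueError):
    """No nDEP equilibrium exists (Re[CM] >= 0)."""


class CalibrationError(DepSpringError, RuntimeError):
    """Bead calibration produced a non-physical normalization factor."""


class ValidationError(DepSpringError, ValueError):
    """A trajectory or segment fails a structural precondition."""
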