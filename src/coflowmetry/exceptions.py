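"""Exception hierarchy for coflowmetry.

Every error raised by the library derives from :class:`CoflowmetryError`
so callers can distinguish physics/data failures from programming errors.
"""


class CoflowmetryError(Exception):
    """Base class for all coflowmetry errors."""


class SingularGeometryError(CoflowmetryError, ValueError):
    """An interface fraction of exactly 0 or 1 collapses one stream's duct."""


class DomainError(CoflowmetryError, ValueError):
    """An input lies outside the physical domain of a formula."""


class InvalidCorrectionModelError(CoflowmetryError, ValueError):
    """The resistance-correction line makes the steady-state map non-invertible."""


class TimeConstantProfileError(CoflowmetryError, ValueError):
    """The time-constant profile is non-positive over the requested range."""


class IntegrationError(CoflowmetryError, RuntimeError):
    """The interface ODE could not be advanced without leaving (0, 1)."""


class GridError(CoflowmetryError, ValueError):
    """A trace's time grid is not uniform to within tolerance."""


class InsufficientDataError(CoflowmetryError, ValueError):
    """Too few samples or calibration points for the requested estimate."""


class SteadyWindowNotFoundError(CoflowmetryError, RuntimeError):
    """No quasi-steady interface window exists in any on-phase.

    This is the failure mode of a heavily compliant circuit: the interface
    keeps drifting through the whole on-phase, so no flat window yields a
    trustworthy viscosity.
    """


class FitFailureError(CoflowmetryError, RuntimeError):
    """A nonlinear fit did not converge or the model is unidentifiable."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class UndefinedAIError(CoflowmetryError, ValueError):
    """The stasis intensity trace is flat; the aggregation index is undefined."""


class DegenerateImageError(CoflowmetryError, ValueError):
    """The ROI contains a single phase; no interface can be extracted."""


class NoisyInterfaceError(CoflowmetryError, ValueError):
    """Fewer than half of the image columns yielded a clean single crossing."""


class UntrackableError(CoflowmetryError, RuntimeError):
    """Every velocimetry block was rejected (no reliable correlation peak)."""


class ConfigError(CoflowmetryError, ValueError):
    """A run configuration failed validation."""
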