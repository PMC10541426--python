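"""Exception hierarchy for the simulator."""


class AirwayRFAError(Exception):
    """Base class for all package errors."""


class GeometryError(AirwayRFAError):
    """Non-physical or inconsistent geometry parameters."""


class SizingError(GeometryError):
    """Geometry cannot be resolved at the requested voxel spacing."""


class ConfigurationError(AirwayRFAError):
    """A run was configured inconsistently (missing source, bad labels, ...)."""


class SolverError(AirwayRFAError):
    """The sparse linear solve failed to converge."""

    def __init__(self, message: str, iterations: int | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


class StabilityError(AirwayRFAError):
    """An explicit time step exceeded the diffusion stability bound."""
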