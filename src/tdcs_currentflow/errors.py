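"""Exception hierarchy for the current-flow modelling pipeline."""


class CurrentFlowError(Exception):
    """Base class for all package errors."""


class ValidationError(CurrentFlowError, ValueError):
    """Invalid parameter values or violated preconditions."""


class GeometryError(CurrentFlowError):
    """Geometry does not fit the grid or is otherwise unrealisable."""


class PlacementError(CurrentFlowError):
    """Electrode pad/gel could not be placed at the requested site."""


class ZeroContactError(CurrentFlowError):
    """No gel-skin interface exists for a placed electrode."""


class ConfigurationError(CurrentFlowError):
    """Missing or inconsistent configuration (e.g. unmapped tissue label)."""


class ConnectivityError(CurrentFlowError):
    """Conductive domain is disconnected between the electrode terminals."""


class SolverError(CurrentFlowError):
    """Iterative solve failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FormatError(CurrentFlowError):
    """File content does not match the expected on-disk format."""
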