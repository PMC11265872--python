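"""Exception hierarchy for corneasim."""


class CorneaSimError(Exception):
    """Base class for all corneasim errors."""


class InvalidGeometryError(CorneaSimError, ValueError):
    """Geometric parameters are inconsistent (e.g. chord longer than diameter)."""


class InvalidDamageError(CorneaSimError, ValueError):
    """Damage parameters outside their admissible range."""


class DegenerateElementError(CorneaSimError, ValueError):
    """A structural element has collapsed to zero length (stretch <= 0)."""


class ConvergenceError(CorneaSimError, RuntimeError):
    """Nonlinear solve failed to reach the requested tolerance."""

    def __init__(self, message, residual_norm=None, step=None):
        super().__init__(message)
        self.residual_norm = residual_norm
        self.step = step


class ConfigError(CorneaSimError, ValueError):
    """Configuration file failed validation."""
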