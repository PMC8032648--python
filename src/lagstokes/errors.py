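"""Exception hierarchy shared across the package."""


class LagStokesError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LagStokesError, ValueError):
    """Invalid physical or numerical configuration (e.g. viscosity <= 0)."""


class DomainError(LagStokesError, ValueError):
    """Geometry violates the flow domain (e.g. source below a no-slip wall)."""


class ShapeError(LagStokesError, ValueError):
    """Array shapes or index sets do not match."""


class NumericalError(LagStokesError, RuntimeError):
    """Ill-conditioned or numerically inconsistent computation."""


class ModelContractError(LagStokesError, RuntimeError):
    """A ShapeModel broke its contract (e.g. element enumeration changed)."""


class GeometryError(LagStokesError, ValueError):
    """Invalid geometry (self-intersection, wall penetration, ...)."""
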