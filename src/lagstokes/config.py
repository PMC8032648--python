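"""Run configuration: YAML schema, validation, provenance.

A :class:`RunConfig` collects everything a command-line run needs — fluid
and kernel settings, model selection and parameters, grid sizes, ODE
tolerances and output paths — validates it before any computation, and can
emit a resolved copy next to the outputs for provenance.

Human-facing units: lengths in micrometers, frequencies in Hz, angles in
degrees; everything is converted to SI (m, s, Pa s, N, rad) on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .kernels import Domain, KernelConfig

__all__ = ["RunConfig", "load_config", "UM", "pN", "fW"]

UM = 1e-6   # micrometer in meters
pN = 1e-12  # piconewton in newtons
fW = 1e-15  # femtowatt in watts

_KNOWN_MODELS = ("cilium", "cilia_pair", "three_sphere", "sphere")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (SI units internally)."""

    model: str = "cilium"
    viscosity: float = 1e-3                  # Pa s
    domain: str = "half_space_wall"
    length_um: float = 10.0                  # cilium length
    n_segments: int = 20
    radius_um: float = 0.1
    d_um: float = 18.0                       # pair separation
    psi_deg: float = 0.0
    omega0_hz: float = 32.0                  # intrinsic beat frequency
    grid_m: int = 16
    rtol: float = 1e-10
    atol: float = 1e-12
    max_cycles: int = 200
    seed: int = 0                            # randomized fixtures only
    out: Optional[str] = None
    pattern: dict = field(default_factory=dict)  # BeatPattern overrides (rad)

    def __post_init__(self):
        if self.model not in _KNOWN_MODELS:
            raise ConfigError(
                f"unknown model {self.model!r}; choose from {_KNOWN_MODELS}"
            )
        if self.viscosity <= 0:
            raise ConfigError("viscosity must be positive")
        Domain(self.domain)  # raises on bad value
        for name in ("length_um", "radius_um", "d_um", "omega0_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.grid_m < 2:
            raise ConfigError("grid_m must be >= 2")
        if not (0 < self.rtol < 1 and 0 < self.atol < 1):
            raise ConfigError("tolerances must be in (0, 1)")

    # ------------------------------------------------------------ derived

    @property
    def kernel(self) -> KernelConfig:
        return KernelConfig(viscosity=self.viscosity, domain=self.domain)

    @property
    def omega0(self) -> float:
        return 2.0 * np.pi * self.omega0_hz  # rad/s

    @property
    def psi(self) -> float:
        return np.deg2rad(self.psi_deg)

    # ------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def write_resolved(self, path) -> None:
        """Emit the resolved configuration (with hash) next to run outputs."""
        payload = self.to_dict()
        payload["config_hash"] = self.config_hash()
        with open(path, "w") as f:
            yaml.safe_dump(payload, f, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return RunConfig.from_dict(data)
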