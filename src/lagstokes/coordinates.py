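"""Shape models over generalized coordinates and the friction matrix Γ.

A shape-changing surface constrained to ``n`` generalized coordinates
``q = (q_1, ..., q_n)`` moves with surface velocity

    v(x) = sum_i w_i(x; q) qdot_i ,      w_i = dx/dq_i ,

and exerts a traction density ``f(x) = sum_j g_j(x; q) qdot_j`` on the fluid,
where ``g_j`` is the traction induced by the unit velocity field ``w_j``
(resistance solve).  The generalized friction matrix

    Γ_ij(q) = sum_k w_i(x_k) . g_j(x_k) A_k

is symmetric (Lorentz reciprocity) and positive semi-definite; the
hydrodynamic dissipation rate is the quadratic form ``qdot . Γ . qdot``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ModelContractError, NumericalError, ShapeError
from .kernels import KernelConfig, ResistanceSolver
from .sample import SurfaceSample

__all__ = [
    "CoordSpec",
    "ShapeModel",
    "VelocityBasis",
    "FrictionMatrix",
    "velocity_basis",
    "force_basis",
    "friction_from_basis",
    "friction_matrix",
    "generalized_forces",
    "dissipation_rate",
]

COORD_KINDS = ("periodic", "linear", "rigid_translation", "rigid_rotation")


@dataclass(frozen=True)
class CoordSpec:
    """Metadata for one generalized coordinate.

    ``kind`` is one of ``periodic`` (period 2*pi), ``linear``,
    ``rigid_translation`` or ``rigid_rotation``.  Rigid coordinates carry the
    lab-frame ``axis`` along which they translate/rotate.  ``scale`` is the
    typical magnitude of the coordinate, used to set default finite-difference
    steps.
    """

    kind: str = "linear"
    unit: str = ""
    axis: Optional[tuple] = None
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in COORD_KINDS:
            raise ShapeError(f"unknown coordinate kind {self.kind!r}")
        if self.kind in ("rigid_translation", "rigid_rotation") and self.axis is None:
            raise ShapeError(f"{self.kind} coordinate requires an axis")
        if self.scale <= 0:
            raise ShapeError("coordinate scale must be > 0")

    @property
    def periodic(self) -> bool:
        return self.kind == "periodic"


@dataclass(frozen=True)
class ShapeModel:
    """Map from generalized coordinates to a discrete surface.

    ``generate(q)`` must return samples with an identical element enumeration
    (same count, same areas) for nearby ``q`` so that finite differences of
    element positions are well defined.

    ``analytic_basis(q)``, if provided, returns the exact derivative arrays
    ``w[i, k, :] = dx_k/dq_i`` and is preferred over finite differences.
    """

    name: str
    n_coords: int
    generate: Callable[[np.ndarray], SurfaceSample]
    coords: Sequence[CoordSpec]
    analytic_basis: Optional[Callable[[np.ndarray], np.ndarray]] = None
    reference_point: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.coords) != self.n_coords:
            raise ShapeError("coords metadata length must equal n_coords")

    def check_q(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float).ravel()
        if q.shape != (self.n_coords,):
            raise ShapeError(
                f"model {self.name!r} expects {self.n_coords} coordinates"
            )
        return q


@dataclass(frozen=True)
class VelocityBasis:
    """Per-coordinate surface velocity fields ``w[i, k, :] = dx_k/dq_i``."""

    w: np.ndarray  # (n_coords, n_elements, 3)
    sample: SurfaceSample

    def __post_init__(self):
        if self.w.ndim != 3 or self.w.shape[1:] != (len(self.sample), 3):
            raise ShapeError("basis shape must be (n_coords, n_elements, 3)")


@dataclass(frozen=True)
class FrictionMatrix:
    """Symmetric positive-(semi)definite generalized friction matrix.

    Entry (i, j) has units force-unit_i * s / coordinate-unit_j; coordinate
    unit labels are carried along for I/O but all numerics are SI-internal.
    """

    matrix: np.ndarray
    units: tuple = ()
    coord_names: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError("friction matrix must be square")
        if not np.all(np.isfinite(m)):
            raise NumericalError("non-finite entries in friction matrix")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def asymmetry(self) -> float:
        m = self.matrix
        scale = np.abs(m).max()
        if scale == 0:
            return 0.0
        return float(np.abs(m - m.T).max() / scale)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(0.5 * (self.matrix + self.matrix.T))

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)

    def to_csv(self, path) -> None:
        """Standalone CSV export with a header naming coordinates and units."""
        import pandas as pd

        n = self.n
        names = self.coord_names or tuple(f"q{i+1}" for i in range(n))
        units = self.units or ("",) * n
        cols = [f"{nm}[{u}]" if u else nm for nm, u in zip(names, units)]
        pd.DataFrame(self.matrix, index=cols, columns=cols).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FrictionMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        names, units = [], []
        for col in df.columns:
            if col.endswith("]") and "[" in col:
                nm, u = col[:-1].split("[", 1)
            else:
                nm, u = col, ""
            names.append(nm)
            units.append(u)
        return cls(matrix=df.to_numpy(), units=tuple(units),
                   coord_names=tuple(names))


def _as_matrix(gamma) -> np.ndarray:
    return gamma.matrix if isinstance(gamma, FrictionMatrix) else np.asarray(gamma, float)


# --------------------------------------------------------------------------


def velocity_basis(
    model: ShapeModel,
    q,
    fd_step=None,
    scheme: str = "central",
    use_analytic: bool = True,
) -> VelocityBasis:
    """Numerical velocity basis ``w_i(x_k) = dx_k/dq_i`` at configuration q.

    Central differences by default (O(eps^2)); ``scheme="forward"`` for
    models only defined one-sided.  Rigid-translation coordinates yield
    exactly uniform unit vectors along their axis.
    """
    q = model.check_q(q)
    sample = model.generate(q)
    n, N = model.n_coords, len(sample)
    if fd_step is None:
        fd_step = np.array([1e-6 * c.scale for c in model.coords])
    else:
        fd_step = np.broadcast_to(np.asarray(fd_step, dtype=float), (n,)).copy()
    if np.any(fd_step <= 0):
        raise ShapeError("fd_step must be positive")

    if use_analytic and model.analytic_basis is not None:
        w = np.asarray(model.analytic_basis(q), dtype=float)
        if w.shape != (n, N, 3):
            raise ModelContractError("analytic_basis returned wrong shape")
        return VelocityBasis(w=w, sample=sample)

    w = np.empty((n, N, 3))
    for i, spec in enumerate(model.coords):
        if spec.kind == "rigid_translation":
            w[i] = np.asarray(spec.axis, dtype=float)
            continue
        if spec.kind == "rigid_rotation":
            axis = np.asarray(spec.axis, dtype=float)
            w[i] = np.cross(axis, sample.points - np.asarray(model.reference_point))
            continue
        eps = fd_step[i]
        dq = np.zeros(n)
        dq[i] = eps
        plus = model.generate(q + dq)
        if scheme == "central":
            minus = model.generate(q - dq)
            _check_enumeration(sample, plus, model.name)
            _check_enumeration(sample, minus, model.name)
            w[i] = (plus.points - minus.points) / (2.0 * eps)
        elif scheme == "forward":
            _check_enumeration(sample, plus, model.name)
            w[i] = (plus.points - sample.points) / eps
        else:
            raise ShapeError(f"unknown differencing scheme {scheme!r}")
    return VelocityBasis(w=w, sample=sample)


def _check_enumeration(ref: SurfaceSample, other: SurfaceSample, name: str):
    if len(other) != len(ref):
        raise ModelContractError(
            f"model {name!r} changed element count under perturbation"
        )
    if not np.allclose(other.areas, ref.areas, rtol=1e-8):
        raise ModelContractError(
            f"model {name!r} changed element areas under perturbation"
        )


def force_basis(
    basis: VelocityBasis,
    config: KernelConfig,
    solver: Optional[ResistanceSolver] = None,
) -> np.ndarray:
    """Normalized traction fields ``g_j`` conjugate to the velocity basis.

    Each ``g_j`` is the resistance solve of ``w_j`` taken at unit generalized
    velocity (alpha_j = 1 coordinate-unit/s); by linearity the result is
    independent of that normalization.
    """
    if solver is None:
        solver = ResistanceSolver(basis.sample, config)
    return solver.solve(basis.w)


def friction_from_basis(
    basis: VelocityBasis,
    config: KernelConfig,
    asym_tol: float = 1e-4,
    solver: Optional[ResistanceSolver] = None,
    units: tuple = (),
    coord_names: tuple = (),
    name: str = "",
) -> FrictionMatrix:
    """Assemble Γ by quadrature: Γ_ij = sum_k w_i(x_k) . g_j(x_k) A_k.

    The matrix is checked for asymmetry (beyond ``asym_tol`` relative is a
    :class:`NumericalError`: discretization noise should be tiny because the
    collocation matrix is itself symmetric) and then symmetrized.
    """
    g = force_basis(basis, config, solver=solver)
    gamma = np.einsum("ikx,jkx,k->ij", basis.w, g, basis.sample.areas)
    fm = FrictionMatrix(matrix=gamma, units=units, coord_names=coord_names)
    if fm.asymmetry() > asym_tol:
        raise NumericalError(
            f"friction matrix asymmetry {fm.asymmetry():.2e} exceeds "
            f"tolerance {asym_tol:.1e}" + (f" for model {name!r}" if name else "")
        )
    return FrictionMatrix(
        matrix=0.5 * (gamma + gamma.T), units=fm.units, coord_names=fm.coord_names
    )


def friction_matrix(
    model: ShapeModel,
    q,
    config: KernelConfig,
    fd_step=None,
    asym_tol: float = 1e-4,
    solver: Optional[ResistanceSolver] = None,
    basis: Optional[VelocityBasis] = None,
) -> FrictionMatrix:
    """Generalized friction matrix Γ(q) of a shape model (see module docs)."""
    if basis is None:
        basis = velocity_basis(model, q, fd_step=fd_step)
    return friction_from_basis(
        basis,
        config,
        asym_tol=asym_tol,
        solver=solver,
        units=tuple(c.unit for c in model.coords),
        coord_names=tuple(f"q{i+1}" for i in range(model.n_coords)),
        name=model.name,
    )


def generalized_forces(gamma, qdot) -> np.ndarray:
    """Generalized friction forces P_i = sum_j Γ_ij qdot_j."""
    m = _as_matrix(gamma)
    qdot = np.asarray(qdot, dtype=float)
    if qdot.shape != (m.shape[0],):
        raise ShapeError("qdot dimension mismatch")
    return m @ qdot


def dissipation_rate(gamma, qdot, tol: float = 1e-9) -> float:
    """Hydrodynamic dissipation rate R = qdot . Γ . qdot (W); must be >= 0."""
    m = _as_matrix(gamma)
    qdot = np.asarray(qdot, dtype=float)
    r = float(qdot @ m @ qdot)
    scale = float(np.abs(m).max() * (qdot @ qdot)) or 1.0
    if r < -tol * scale:
        raise NumericalError(
            f"negative dissipation rate {r:.3e} violates positive "
            "semi-definiteness of the friction matrix"
        )
    return r
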