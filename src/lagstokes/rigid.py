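"""Rigid-body motion of self-propelled microswimmers.

Six rigid-body generalized coordinates (translations along and rotations
about the material-frame axes), the 6x6 grand friction matrix (inverse
mobility matrix), free-swimmer solves under zero net force and torque, and
exact-exponential frame updates.

Conventions: a :class:`MaterialFrame` stores the reference point ``x0`` and
basis row-matrix ``E`` with rows ``e_1, e_2, e_3`` (lab components).  A body
point with material coordinates ``x'`` sits at ``x = x0 + x' @ E``.
Translational and rotational velocity components (v, Omega) are expressed in
the material basis; the conjugate generalized friction forces are
``P_1..P_3 = F . e_i`` and ``P_4..P_6 = M . e_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.spatial.transform import Rotation

from .coordinates import FrictionMatrix, VelocityBasis, friction_from_basis
from .errors import ConfigError, NumericalError, ShapeError
from .kernels import KernelConfig, ResistanceSolver, total_force_torque
from .sample import SurfaceSample

__all__ = [
    "MaterialFrame",
    "RigidVelocity",
    "rigid_velocity_field",
    "rigid_velocity_basis",
    "grand_friction_matrix",
    "solve_free_swimmer",
    "step_frame",
    "ShapeProtocol",
    "free_swim",
]

RIGID_COORD_NAMES = ("v1", "v2", "v3", "O1", "O2", "O3")


@dataclass(frozen=True)
class MaterialFrame:
    """Reference point and right-handed orthonormal triad of a swimmer."""

    x0: np.ndarray
    E: np.ndarray  # (3, 3); row i = e_i in lab components

    def __post_init__(self):
        x0 = np.asarray(self.x0, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if x0.shape != (3,) or E.shape != (3, 3):
            raise ShapeError("frame needs x0 (3,) and E (3, 3)")
        if not np.allclose(E @ E.T, np.eye(3), atol=1e-10):
            raise ShapeError("material frame triad is not orthonormal to 1e-10")
        if np.linalg.det(E) < 0:
            raise ShapeError("material frame triad must be right-handed")
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "E", E)

    @classmethod
    def identity(cls, x0=(0.0, 0.0, 0.0)) -> "MaterialFrame":
        return cls(x0=np.asarray(x0, dtype=float), E=np.eye(3))

    def to_lab(self, body_points: np.ndarray) -> np.ndarray:
        return self.x0 + np.atleast_2d(body_points) @ self.E

    def vectors_to_lab(self, body_vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(body_vectors) @ self.E

    def orthonormality_error(self) -> float:
        return float(np.abs(self.E @ self.E.T - np.eye(3)).max())


@dataclass(frozen=True)
class RigidVelocity:
    """Rigid-body velocity: components in the material basis."""

    v: np.ndarray      # (3,) translational, m/s
    omega: np.ndarray  # (3,) rotational, rad/s

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        w = np.asarray(self.omega, dtype=float)
        if v.shape != (3,) or w.shape != (3,):
            raise ShapeError("rigid velocity needs v (3,) and omega (3,)")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
            raise ShapeError("non-finite rigid velocity")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "omega", w)

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.v, self.omega])


def rigid_velocity_field(
    sample: SurfaceSample, frame: MaterialFrame, rv: RigidVelocity
) -> np.ndarray:
    """Surface velocity v(x_k) = v0 + Omega x (x_k - x0) of a rigid motion."""
    v0 = rv.v @ frame.E
    Omega = rv.omega @ frame.E
    return v0 + np.cross(Omega, sample.points - frame.x0)


def rigid_velocity_basis(sample: SurfaceSample, frame: MaterialFrame) -> VelocityBasis:
    """Analytic velocity basis of the six rigid coordinates."""
    N = len(sample)
    w = np.empty((6, N, 3))
    rel = sample.points - frame.x0
    for i in range(3):
        w[i] = frame.E[i]
        w[3 + i] = np.cross(frame.E[i], rel)
    return VelocityBasis(w=w, sample=sample)


def grand_friction_matrix(
    sample: SurfaceSample,
    frame: MaterialFrame,
    config: KernelConfig,
    solver: Optional[ResistanceSolver] = None,
) -> FrictionMatrix:
    """6x6 rigid-body friction matrix (inverse mobility matrix)."""
    basis = rigid_velocity_basis(sample, frame)
    return friction_from_basis(
        basis,
        config,
        solver=solver,
        units=("m", "m", "m", "rad", "rad", "rad"),
        coord_names=RIGID_COORD_NAMES,
    )


def solve_free_swimmer(
    sample: SurfaceSample,
    frame: MaterialFrame,
    shape_rate_field: np.ndarray,
    config: KernelConfig,
    solver: Optional[ResistanceSolver] = None,
) -> Tuple[RigidVelocity, np.ndarray]:
    """Rigid velocity of a force- and torque-free shape-changing swimmer.

    ``shape_rate_field`` is the lab-frame surface velocity due to the shape
    change alone (the material-frame deformation rate rotated into the lab).
    Solves the 6x6 linear system so that the total traction integrates to
    zero force and torque, and returns (rigid velocity, total traction).
    """
    rate = np.asarray(shape_rate_field, dtype=float)
    if rate.shape != (len(sample), 3):
        raise ShapeError("shape_rate_field must be (N, 3)")
    if solver is None:
        solver = ResistanceSolver(sample, config)
    basis = rigid_velocity_basis(sample, frame)
    f_act = solver.solve(rate)
    F_act, M_act = total_force_torque(sample, f_act, frame.x0)
    P_act = np.concatenate([frame.E @ F_act, frame.E @ M_act])
    gamma = friction_from_basis(basis, config, solver=solver).matrix
    try:
        u = np.linalg.solve(gamma, -P_act)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular grand friction matrix") from exc
    g = solver.solve(basis.w)
    traction = f_act + np.einsum("i,ikx->kx", u, g)
    rv = RigidVelocity(v=u[:3], omega=u[3:])
    return rv, traction


def step_frame(frame: MaterialFrame, rv: RigidVelocity, dt: float) -> MaterialFrame:
    """Advance a material frame by the exact rotation exp(Omega dt).

    The triad is rotated by the finite rotation generated by the lab-frame
    angular velocity (no Euler drift), then re-orthonormalized via a polar
    projection guard; the reference point advances with the lab-frame
    translational velocity.
    """
    Omega_lab = rv.omega @ frame.E
    R = Rotation.from_rotvec(Omega_lab * dt).as_matrix()
    E_new = frame.E @ R.T  # rows e_i -> R e_i
    # polar projection: nearest orthonormal matrix
    U, _, Vt = np.linalg.svd(E_new)
    E_new = U @ Vt
    x0_new = frame.x0 + (rv.v @ frame.E) * dt
    return MaterialFrame(x0=x0_new, E=E_new)


# --------------------------------------------------------------------------
# free-swimmer time integration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeProtocol:
    """Prescribed shape dynamics in material coordinates.

    ``shape(t)`` returns the body-frame surface sample and the body-frame
    deformation-rate field at time t; the element enumeration must not
    change with t.
    """

    shape: Callable[[float], Tuple[SurfaceSample, np.ndarray]]
    period: Optional[float] = None


def _quat_mult(a, b):
    # scalar-last quaternions (x, y, z, w)
    ax, ay, az, aw = a
    bx, by, bz, bw = b
    return np.array(
        [
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
            aw * bw - ax * bx - ay * by - az * bz,
        ]
    )


def free_swim(
    protocol: ShapeProtocol,
    config: KernelConfig,
    frame0: Optional[MaterialFrame] = None,
    t_span: Tuple[float, float] = (0.0, 1.0),
    rtol: float = 1e-8,
    atol: float = 1e-11,
    t_eval=None,
):
    """Integrate rigid-body motion of a force/torque-free swimmer.

    State: reference point and orientation quaternion; at each step the
    free-swimmer problem is solved for the prescribed shape rate.  Returns
    ``(t, x0(t), frames)`` with frames reconstructed at the sample times.
    """
    if frame0 is None:
        frame0 = MaterialFrame.identity()
    q0 = Rotation.from_matrix(frame0.E.T).as_quat()
    y0 = np.concatenate([frame0.x0, q0])

    def frame_from_state(y):
        quat = y[3:7]
        quat = quat / np.linalg.norm(quat)
        E = Rotation.from_quat(quat).as_matrix().T
        U, _, Vt = np.linalg.svd(E)
        return MaterialFrame(x0=y[:3], E=U @ Vt)

    def rhs(t, y):
        frame = frame_from_state(y)
        body_sample, body_rate = protocol.shape(t)
        lab_sample = SurfaceSample(
            points=frame.to_lab(body_sample.points),
            areas=body_sample.areas,
            element_radius=body_sample.element_radius,
        )
        rate_lab = frame.vectors_to_lab(body_rate)
        rv, _ = solve_free_swimmer(lab_sample, frame, rate_lab, config)
        v_lab = rv.v @ frame.E
        Omega_lab = rv.omega @ frame.E
        quat = y[3:7] / np.linalg.norm(y[3:7])
        dquat = 0.5 * _quat_mult(np.array([*Omega_lab, 0.0]), quat)
        return np.concatenate([v_lab, dquat])

    sol = solve_ivp(rhs, t_span, y0, method="RK45", rtol=rtol, atol=atol,
                    dense_output=True, t_eval=t_eval)
    if not sol.success:
        raise NumericalError(f"free-swimmer integration failed: {sol.message}")
    frames = [frame_from_state(y) for y in sol.y.T]
    return sol.t, sol.y[:3].T, frames
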