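"""Equations of motion: balance of active driving and hydrodynamic friction.

At zero Reynolds number inertia is negligible, so the dynamics of the
generalized coordinates follows from the instantaneous force balance
``Q_i = P_i = sum_j Γ_ij qdot_j``, i.e. ``qdot = Γ(q)^{-1} Q(q)``.  Active
driving forces ``Q_i(q_i)`` coarse-grain internal processes (e.g. molecular
motors); they are assumed load-independent here and each depends only on its
own coordinate.  For a single periodic coordinate the driving force is
calibrated so the isolated unit runs at a constant reference phase speed:
``Q(phi) = omega0 * Γ_11(phi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp

from .coordinates import FrictionMatrix
from .errors import ConfigError, NumericalError, ShapeError
from .tables import FrictionTable

__all__ = [
    "DrivingForce",
    "Role",
    "equation_of_motion",
    "calibrate_driving_force",
    "integrate",
    "measure_period",
    "Trajectory",
]


GammaSource = Union[FrictionTable, Callable[[np.ndarray], np.ndarray]]


def _gamma_fn(source: GammaSource) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(source, FrictionTable):
        return lambda q: source.interpolate(q).matrix
    return lambda q: np.asarray(source(q), dtype=float)


@dataclass(frozen=True)
class DrivingForce:
    """Per-coordinate active driving forces Q_i(q_i).

    Each component is a scalar callable of its own coordinate only (the
    load-independence and locality assumption of the model).
    """

    components: tuple

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return np.array([f(qi) for f, qi in zip(self.components, q, strict=True)])

    @property
    def n(self) -> int:
        return len(self.components)

    @classmethod
    def constant(cls, values) -> "DrivingForce":
        vals = np.asarray(values, dtype=float)
        return cls(components=tuple((lambda v: (lambda q: v))(v) for v in vals))


def equation_of_motion(gamma, Q) -> np.ndarray:
    """Solve the force balance Γ qdot = Q for the generalized velocities.

    Direct symmetric factorization (never an explicit inverse); the residual
    is verified to < 1e-10 relative.
    """
    m = gamma.matrix if isinstance(gamma, FrictionMatrix) else np.asarray(gamma, float)
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (m.shape[0],):
        raise ShapeError("driving force dimension mismatch")
    try:
        qdot = scipy.linalg.solve(m, Q, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular friction matrix: Γ must be positive definite away from "
            "singular configurations"
        ) from exc
    qnorm = np.linalg.norm(Q)
    if qnorm > 0:
        resid = np.linalg.norm(m @ qdot - Q) / qnorm
        if resid > 1e-10:
            raise NumericalError(
                f"force-balance solve residual {resid:.2e} exceeds 1e-10; "
                "friction matrix may be near-singular"
            )
    return qdot


def calibrate_driving_force(table: FrictionTable, omega0: float) -> DrivingForce:
    """Driving force for an isolated unit with one periodic coordinate.

    Requiring constant phase speed ``phidot = omega0`` in the single-unit
    force balance ``Q(phi) = Γ_11(phi) phidot`` gives
    ``Q(phi) = omega0 * Γ_11(phi)``.
    """
    if table.n_coords != 1 or not table.periodic[0]:
        raise ConfigError(
            "calibration requires a single-coordinate periodic friction table"
        )
    g11 = table.entry_function(0, 0)
    return DrivingForce(components=(lambda phi: omega0 * g11(phi),))


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Role:
    """Role of one coordinate during integration.

    kind: "free" (evolves by force balance), "prescribed" (q_i(t) given),
    "constrained" (qdot_i = 0; reports the constraining force), or
    "external" (free, with an added external generalized force).
    """

    kind: str = "free"
    q_of_t: Optional[Callable[[float], float]] = None
    qdot_of_t: Optional[Callable[[float], float]] = None
    Q_ext: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.kind not in ("free", "prescribed", "constrained", "external"):
            raise ConfigError(f"unknown coordinate role {self.kind!r}")
        if self.kind == "prescribed" and (self.q_of_t is None or self.qdot_of_t is None):
            raise ConfigError("prescribed role needs q_of_t and qdot_of_t")


@dataclass
class Trajectory:
    """Time series of a force-balance integration (SI units)."""

    t: np.ndarray
    q: np.ndarray       # (T, n)
    qdot: np.ndarray    # (T, n)
    P: np.ndarray       # (T, n) generalized friction forces
    dissipation: np.ndarray  # (T,)
    success: bool = True
    message: str = ""

    def to_dataframe(self):
        import pandas as pd

        n = self.q.shape[1]
        data = {"t": self.t}
        for i in range(n):
            data[f"q{i+1}"] = self.q[:, i]
        for i in range(n):
            data[f"qdot{i+1}"] = self.qdot[:, i]
        for i in range(n):
            data[f"P{i+1}"] = self.P[:, i]
        data["dissipation"] = self.dissipation
        return pd.DataFrame(data)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("t", "q", "qdot", "P", "dissipation"):
                f.create_dataset(name, data=getattr(self, name))


def integrate(
    gamma_source: GammaSource,
    driving: DrivingForce,
    q0,
    t_span,
    roles: Optional[Sequence[Role]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval=None,
    events=None,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the force-balance dynamics ``Γ(q) qdot = Q(q)``.

    Prescribed and constrained coordinates are moved to the right-hand side:
    with free indices F and driven indices D,

        Γ_FF qdot_F = Q_F - Γ_FD qdot_D(t),

    and the conjugate friction forces ``P_i = (Γ qdot)_i`` of driven
    coordinates (the constraining forces) are reported along the trajectory.
    """
    q0 = np.asarray(q0, dtype=float)
    n = q0.size
    if roles is None:
        roles = [Role()] * n
    if len(roles) != n:
        raise ShapeError("one role per coordinate required")
    gamma = _gamma_fn(gamma_source)
    free = np.array([r.kind in ("free", "external") for r in roles])
    idx_free = np.where(free)[0]
    idx_driv = np.where(~free)[0]

    def q_full(t, qf):
        q = np.empty(n)
        q[idx_free] = qf
        for i in idx_driv:
            q[i] = roles[i].q_of_t(t) if roles[i].kind == "prescribed" else q0[i]
        return q

    def qdot_driv(t):
        return np.array(
            [
                roles[i].qdot_of_t(t) if roles[i].kind == "prescribed" else 0.0
                for i in idx_driv
            ]
        )

    if not free.any():
        # fully driven system: no ODE to solve, just report friction forces
        tt = np.linspace(*t_span, 101) if t_eval is None else np.asarray(t_eval)
        qs = np.array([q_full(t, np.empty(0)) for t in tt])
        qds = np.array([qdot_driv(t) for t in tt])  # idx_driv is 0..n-1 here
        Ps = np.array([gamma(q) @ qd for q, qd in zip(qs, qds)])
        diss = np.einsum("ti,ti->t", qds, Ps)
        return Trajectory(t=tt, q=qs, qdot=qds, P=Ps, dissipation=diss)

    def rhs(t, qf):
        q = q_full(t, qf)
        G = gamma(q)
        Qf = driving(q)[idx_free]
        for j, i in enumerate(idx_free):
            if roles[i].kind == "external" and roles[i].Q_ext is not None:
                Qf[j] = Qf[j] + roles[i].Q_ext(t)
        if idx_driv.size:
            Qf = Qf - G[np.ix_(idx_free, idx_driv)] @ qdot_driv(t)
        return equation_of_motion(G[np.ix_(idx_free, idx_free)], Qf)

    sol = solve_ivp(
        rhs,
        t_span,
        q0[idx_free],
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
        t_eval=t_eval,
        events=events,
    )
    if not sol.success:
        raise NumericalError(f"integration failed: {sol.message}")

    tt = sol.t
    qs = np.empty((tt.size, n))
    qds = np.empty((tt.size, n))
    Ps = np.empty((tt.size, n))
    diss = np.empty(tt.size)
    for k, (t, qf) in enumerate(zip(tt, sol.y.T)):
        q = q_full(t, qf)
        qd = np.empty(n)
        qd[idx_free] = rhs(t, qf)
        qd[idx_driv] = qdot_driv(t)
        G = gamma(q)
        P = G @ qd
        qs[k], qds[k], Ps[k] = q, qd, P
        diss[k] = float(qd @ P)
    traj = Trajectory(t=tt, q=qs, qdot=qds, P=Ps, dissipation=diss,
                      success=sol.success, message=str(sol.message))
    traj.sol = sol  # expose dense output and events for downstream analysis
    return traj


def measure_period(
    gamma_source: GammaSource,
    driving: DrivingForce,
    n_periods: int = 10,
    phi0: float = 0.0,
    omega_guess: float = 1.0,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> float:
    """Mean beat period of a single-coordinate periodic unit.

    Integrates until the phase has advanced ``n_periods * 2 pi`` (event
    detection on dense output) and returns the elapsed time divided by the
    number of periods.
    """
    target = phi0 + 2.0 * np.pi * n_periods

    def reached(t, y):
        return y[0] - target

    reached.terminal = True
    reached.direction = 1
    horizon = 4.0 * np.pi * n_periods / abs(omega_guess)
    traj = integrate(
        gamma_source,
        driving,
        [phi0],
        (0.0, horizon),
        rtol=rtol,
        atol=atol,
        events=reached,
    )
    t_events = traj.sol.t_events[0]
    if len(t_events) == 0:
        raise NumericalError("phase did not complete the requested cycles")
    return float(t_events[0]) / n_periods
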