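"""Wall-anchored beating cilia and hydrodynamic synchronization of a pair.

Each cilium is a slender filament anchored to the no-slip wall z = 0 whose
periodic beat is parameterized by a single 2*pi-periodic phase variable phi.
The shipped synthetic beat pattern emulates the ciliary strokes of ciliated
protists: an *effective stroke* sweeping an extended filament through the
+y half-space, and a *recovery stroke* returning the filament curled close
to the wall, with a lateral (x) excursion that makes the beat fully
three-dimensional.

A pair of identical cilia with phases (phi_1, phi_2) is a pair of coupled
phase oscillators: the force balance

    Q_1(phi_1) = Gamma_11(phi_1) phidot_1 + Gamma_12(phi_1, phi_2) phidot_2
    Q_2(phi_2) = Gamma_12(phi_1, phi_2) phidot_1 + Gamma_22(phi_2) phidot_2

with driving forces calibrated so an isolated cilium beats at omega_0.  The
cross-friction Gamma_12 encodes the hydrodynamic interaction and decays as
1/d^3 with base-point distance d (wall-parallel point-force far field).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .coordinates import CoordSpec, ShapeModel
from .dynamics import DrivingForce, calibrate_driving_force, equation_of_motion
from .errors import ConfigError, GeometryError, NumericalError, ShapeError
from .kernels import Domain, KernelConfig, mobility_tensor
from .sample import SurfaceSample, merge_samples
from .tables import FrictionTable, build_table, trig_interp_coeffs, trig_interp_eval

__all__ = [
    "BeatPattern",
    "synthetic_beat_pattern",
    "cilium_shape_model",
    "cilia_pair_model",
    "CiliaPairConfig",
    "PairTables",
    "single_cilium_table",
    "pair_tables",
    "pair_driving_force",
    "integrate_pair",
    "lyapunov_exponent",
    "steady_state_phase_difference",
    "SteadyStateResult",
    "scan_and_fit",
    "ScanResult",
    "wall_parallel_decay_exponent",
    "wrap_phase_difference",
]

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# synthetic beat pattern
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BeatPattern:
    """Parameterized 3-D beat of a wall-anchored cilium.

    The centerline tangent is built from two angles.  The in-plane (y-z)
    inclination from the wall normal is a tilted traveling wave,

        alpha(s, phi) = tilt + sweep * (0.6 + 0.4 s/L) * cos(phi - lag s/L)
                             + curl * (s/L) * cos(2 (phi - lag s/L)),

    and the out-of-plane tilt is ``beta(s, phi) = asym * (s/L) *
    sin(phi - lag s/L)``, giving tangent ``t = (sin beta, cos beta sin
    alpha, cos beta cos alpha)``.  The mean ``tilt`` leans the beat
    envelope toward the effective-stroke axis +y, as in ciliate beats;
    the first harmonic (amplitude growing tipward, phase traveling
    tipward with ``wave_lag``) sweeps the extended filament through the
    +y half-space during the effective stroke and returns it bent closer
    to the wall during recovery; the second harmonic sharpens the
    effective/recovery asymmetry; ``asym`` adds the lateral (x) recovery
    excursion that makes the beat fully three-dimensional (asym = 0
    recovers a planar beat in the y-z plane).  With the default angles
    ``|alpha| < pi/2`` everywhere, so the centerline structurally cannot
    penetrate the wall.

    All lengths in meters, angles in radians; 2*pi-periodic in phi by
    construction.  The effective stroke direction is +y.
    """

    length: float = 10e-6
    tilt: float = 0.85
    sweep: float = 0.55
    curl: float = 0.10
    wave_lag: float = 2.0
    asym: float = 0.4
    n_quad: int = 24  # Gauss points per requested arclength interval

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigError("cilium length must be positive")

    # ---------------------------------------------------------- geometry

    def _angles(self, phi, sigma):
        """alpha, beta and their phi-derivatives at relative arclength sigma."""
        ph = phi - self.wave_lag * sigma
        amp = self.sweep * (0.6 + 0.4 * sigma)
        alpha = (
            self.tilt + amp * np.cos(ph) + self.curl * sigma * np.cos(2.0 * ph)
        )
        beta = self.asym * sigma * np.sin(ph)
        dalpha = -amp * np.sin(ph) - 2.0 * self.curl * sigma * np.sin(2.0 * ph)
        dbeta = self.asym * sigma * np.cos(ph)
        return alpha, beta, dalpha, dbeta

    def tangent(self, phi, sigma):
        """Unit tangent at relative arclength sigma (vectorized)."""
        alpha, beta, _, _ = self._angles(phi, np.asarray(sigma, dtype=float))
        return np.stack(
            [np.sin(beta), np.cos(beta) * np.sin(alpha), np.cos(beta) * np.cos(alpha)],
            axis=-1,
        )

    def _tangent_and_dphi(self, phi, sigma):
        alpha, beta, dalpha, dbeta = self._angles(phi, sigma)
        sa, ca = np.sin(alpha), np.cos(alpha)
        sb, cb = np.sin(beta), np.cos(beta)
        t = np.stack([sb, cb * sa, cb * ca], axis=-1)
        dt = np.stack(
            [
                cb * dbeta,
                -sb * dbeta * sa + cb * ca * dalpha,
                -sb * dbeta * ca - cb * sa * dalpha,
            ],
            axis=-1,
        )
        return t, dt

    def _integrate(self, phi, s, which):
        """Cumulative Gauss-Legendre integration of the tangent (and d/dphi)."""
        s = np.asarray(s, dtype=float)
        if np.any(s < 0) or np.any(s > self.length * (1 + 1e-12)):
            raise ShapeError("arclength outside [0, L]")
        nodes = np.concatenate([[0.0], s])
        xg, wg = np.polynomial.legendre.leggauss(self.n_quad)
        pos = np.zeros((s.size, 3))
        dpos = np.zeros((s.size, 3))
        x = np.zeros(3)
        dx = np.zeros(3)
        for i in range(s.size):
            a, b = nodes[i], nodes[i + 1]
            half = 0.5 * (b - a)
            sg = a + half * (xg + 1.0)
            t, dt = self._tangent_and_dphi(phi, sg / self.length)
            x = x + half * np.einsum("g,gx->x", wg, t)
            dx = dx + half * np.einsum("g,gx->x", wg, dt)
            pos[i] = x
            dpos[i] = dx
        return pos if which == "pos" else (pos, dpos)

    def centerline(self, phi, s) -> np.ndarray:
        """Centerline points (above the base) at arclengths ``s`` (m)."""
        return self._integrate(phi, s, "pos")

    def centerline_and_dphi(self, phi, s):
        """Centerline and its analytic phase derivative d x / d phi."""
        return self._integrate(phi, s, "both")

    # ---------------------------------------------------------- validation

    def validate(self, n_phi: int = 32, n_s: int = 40, clearance: float = 0.0):
        """Reject parameter sets whose centerline penetrates the wall."""
        s = np.linspace(self.length / n_s, self.length, n_s)
        zmin = np.inf
        for phi in np.arange(n_phi) * TWO_PI / n_phi:
            z = self.centerline(phi, s)[:, 2]
            zmin = min(zmin, z.min())
        if zmin <= clearance:
            raise GeometryError(
                f"beat pattern penetrates the wall (min z = {zmin:.3e} m); "
                "adjust sweep/curl parameters"
            )
        return self


def synthetic_beat_pattern(
    length: float = 10e-6,
    tilt: float = 0.85,
    sweep: float = 0.55,
    curl: float = 0.10,
    wave_lag: float = 2.0,
    asym: float = 0.4,
) -> BeatPattern:
    """Construct and validate the synthetic beat pattern (defaults shipped)."""
    return BeatPattern(
        length=length, tilt=tilt, sweep=sweep, curl=curl,
        wave_lag=wave_lag, asym=asym,
    ).validate()


# --------------------------------------------------------------------------
# shape models
# --------------------------------------------------------------------------


def _segment_arclengths(length: float, n_segments: int) -> np.ndarray:
    return (np.arange(n_segments) + 0.5) * length / n_segments


def cilium_shape_model(
    pattern: BeatPattern,
    base=(0.0, 0.0, 0.0),
    n_segments: int = 20,
    radius: float = 0.1e-6,
    name: str = "cilium",
) -> ShapeModel:
    """Single cilium as a chain of blob elements, one periodic coordinate.

    Element k sits at the centerline point of arclength (k + 1/2) L / n,
    carries lateral area 2 pi a (L/n) and blob radius a.
    """
    base = np.asarray(base, dtype=float)
    if abs(base[2]) > 1e-15:
        raise GeometryError("cilium base must lie on the wall plane z = 0")
    n = int(n_segments)
    if n < 10:
        raise ConfigError("need at least 10 segments per cilium")
    seg_len = pattern.length / n
    if seg_len < 2.0 * radius:
        raise ConfigError(
            f"segment spacing {seg_len:.2e} m below element diameter "
            f"{2*radius:.2e} m; reduce n_segments or the radius"
        )
    s = _segment_arclengths(pattern.length, n)
    areas = np.full(n, 2.0 * np.pi * radius * seg_len)
    radii = np.full(n, radius)

    def generate(q):
        pts = base + pattern.centerline(float(q[0]), s)
        return SurfaceSample(points=pts, areas=areas, element_radius=radii)

    def analytic_basis(q):
        _, dpts = pattern.centerline_and_dphi(float(q[0]), s)
        return dpts[None, :, :]

    return ShapeModel(
        name=name,
        n_coords=1,
        generate=generate,
        coords=(CoordSpec(kind="periodic", unit="rad"),),
        analytic_basis=analytic_basis,
    )


@dataclass(frozen=True)
class CiliaPairConfig:
    """Geometry and dynamics parameters of a cilia pair.

    ``d``: base-point separation (m); ``psi``: angle of the separation
    direction with the x axis (rad; the effective stroke of both cilia
    points along +y); ``omega0``: intrinsic beat angular frequency (rad/s).
    """

    d: float = 18e-6
    psi: float = 0.0
    omega0: float = TWO_PI * 32.0
    n_segments: int = 20
    radius: float = 0.1e-6

    def __post_init__(self):
        if self.d <= 0:
            raise ConfigError("separation distance must be positive")
        object.__setattr__(self, "psi", float(np.mod(self.psi, TWO_PI)))

    @property
    def base2(self) -> np.ndarray:
        return self.d * np.array([np.cos(self.psi), np.sin(self.psi), 0.0])


def cilia_pair_model(
    pattern: BeatPattern, pair: CiliaPairConfig, name: str = "cilia_pair"
) -> ShapeModel:
    """Two identical cilia as one combined model with coordinates (phi1, phi2)."""
    s = _segment_arclengths(pattern.length, pair.n_segments)
    n = pair.n_segments
    seg_len = pattern.length / n
    areas = np.full(2 * n, 2.0 * np.pi * pair.radius * seg_len)
    radii = np.full(2 * n, pair.radius)
    base1 = np.zeros(3)
    base2 = pair.base2

    def generate(q):
        p1 = base1 + pattern.centerline(float(q[0]), s)
        p2 = base2 + pattern.centerline(float(q[1]), s)
        return SurfaceSample(
            points=np.concatenate([p1, p2]), areas=areas, element_radius=radii
        )

    def analytic_basis(q):
        _, d1 = pattern.centerline_and_dphi(float(q[0]), s)
        _, d2 = pattern.centerline_and_dphi(float(q[1]), s)
        w = np.zeros((2, 2 * n, 3))
        w[0, :n] = d1
        w[1, n:] = d2
        return w

    return ShapeModel(
        name=name,
        n_coords=2,
        generate=generate,
        coords=(
            CoordSpec(kind="periodic", unit="rad"),
            CoordSpec(kind="periodic", unit="rad"),
        ),
        analytic_basis=analytic_basis,
    )


def _check_no_intersection(pattern, pair, phases) -> None:
    """Minimum inter-cilium clearance across a phase grid."""
    s = _segment_arclengths(pattern.length, pair.n_segments)
    pts = np.array([pattern.centerline(p, s) for p in phases])  # (m, n, 3)
    p1 = pts
    p2 = pts + pair.base2
    # min distance between cilium 1 at phi_a and cilium 2 at phi_b, all pairs
    diff = p1[:, None, :, None, :] - p2[None, :, None, :, :]
    dmin = np.sqrt((diff**2).sum(-1)).min(axis=(2, 3))
    bad = np.argwhere(dmin < 2.0 * pair.radius)
    if bad.size:
        offending = [(float(phases[i]), float(phases[j])) for i, j in bad[:5]]
        raise GeometryError(
            f"cilia intersect at phase pairs {offending} (d = {pair.d*1e6:.1f} um)"
        )


# --------------------------------------------------------------------------
# friction tables for the pair
# --------------------------------------------------------------------------


def single_cilium_table(
    model: ShapeModel, config: KernelConfig, m: int = 24
) -> FrictionTable:
    """Self-friction Γ_11(phi) of an isolated cilium on an m-point phase grid."""
    if m < 8:
        raise ConfigError("need at least 8 phase grid points")
    table = build_table(model, m, config, interpolation="fourier")
    if np.any(table.values[..., 0, 0] <= 0):
        raise NumericalError("non-positive self-friction in single-cilium table")
    return table


@dataclass
class PairTables:
    """Friction tables of a cilia pair.

    ``single``: Γ_11(phi) of the isolated cilium (used for both
    self-frictions; the pair self-friction is virtually independent of the
    other cilium's phase, and ``self_approx_error`` records the measured
    relative error of that replacement).  ``pair2d``: full 2x2 Γ(phi1, phi2)
    on the (m x m) torus grid; its off-diagonal entry is the cross-friction
    coupling the two cilia.
    """

    single: FrictionTable
    pair2d: FrictionTable
    config: CiliaPairConfig
    self_approx_error: float = np.nan
    _c11: np.ndarray = field(default=None, repr=False)
    _c12: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self._c11 = trig_interp_coeffs(self.single.values[:, 0, 0], 1)
        self._c12 = trig_interp_coeffs(self.pair2d.values[:, :, 0, 1], 2)

    def gamma11(self, phi) -> float:
        return float(trig_interp_eval(self._c11, 1, [phi]))

    def gamma12(self, phi1, phi2) -> float:
        return float(trig_interp_eval(self._c12, 2, [phi1, phi2]))

    def gamma(self, q) -> np.ndarray:
        """2x2 friction matrix with single-cilium self-frictions."""
        g12 = self.gamma12(q[0], q[1])
        return np.array(
            [[self.gamma11(q[0]), g12], [g12, self.gamma11(q[1])]]
        )

    def gamma12_l2_norm(self) -> float:
        """Grid-quadrature L2 norm of Γ_12 over the (phi1, phi2) torus."""
        v = self.pair2d.values[:, :, 0, 1]
        cell = (TWO_PI / v.shape[0]) * (TWO_PI / v.shape[1])
        return float(np.sqrt((v**2).sum() * cell))


def pair_tables(
    pattern: BeatPattern,
    pair: CiliaPairConfig,
    config: KernelConfig,
    m: int = 16,
    m_single: Optional[int] = None,
    sym_tol: float = 1e-4,
) -> PairTables:
    """Build single-cilium and pair friction tables on phase grids.

    Asserts the reciprocity symmetry Γ_12 = Γ_21 on the grid, then uses the
    symmetrized entry; measures the self-friction approximation error
    ``max |Γ_11(phi1, phi2) - Γ_11(phi1)| / max Γ_11``.
    """
    if config.domain is not Domain.HALF_SPACE_WALL:
        raise ConfigError("cilia models require the half-space wall domain")
    phases = np.arange(m) * TWO_PI / m
    _check_no_intersection(pattern, pair, phases)
    single_model = cilium_shape_model(
        pattern, n_segments=pair.n_segments, radius=pair.radius
    )
    m1 = m_single if m_single is not None else m
    single = single_cilium_table(single_model, config, m=m1)
    model2 = cilia_pair_model(pattern, pair)
    pair2d = build_table(model2, m, config, interpolation="fourier")
    v = pair2d.values
    g12, g21 = v[:, :, 0, 1], v[:, :, 1, 0]
    denom = np.abs(g12).max() or 1.0
    asym = np.abs(g12 - g21).max() / denom
    if asym > sym_tol:
        raise NumericalError(
            f"cross-friction asymmetry {asym:.2e} exceeds {sym_tol:.1e}"
        )
    # self-friction approximation error against the isolated-cilium table
    g11_single = np.array([single.interpolate([p]).matrix[0, 0] for p in phases])
    err = np.abs(v[:, :, 0, 0] - g11_single[:, None]).max() / g11_single.max()
    return PairTables(
        single=single, pair2d=pair2d, config=pair, self_approx_error=float(err)
    )


# --------------------------------------------------------------------------
# pair dynamics
# --------------------------------------------------------------------------


def wrap_phase_difference(delta) -> np.ndarray:
    """Wrap a phase difference to (-pi, pi]."""
    return -np.mod(-np.asarray(delta) + np.pi, TWO_PI) + np.pi


def pair_driving_force(tables: PairTables, omega0: Optional[float] = None) -> DrivingForce:
    """Calibrated driving forces Q_i(phi) = omega0 * Γ_11(phi), both cilia."""
    w0 = tables.config.omega0 if omega0 is None else omega0
    single = calibrate_driving_force(tables.single, w0)
    return DrivingForce(components=(single.components[0], single.components[0]))


def _pair_rhs(tables: PairTables, driving: DrivingForce):
    def rhs(t, y):
        G = tables.gamma(y)
        det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
        if det <= 0:
            raise NumericalError(
                "singular 2x2 pair system (|C1 C2| >= 1); cilia too close "
                "for the far-field phase reduction"
            )
        Q = driving(y)
        return np.array(
            [
                (G[1, 1] * Q[0] - G[0, 1] * Q[1]) / det,
                (G[0, 0] * Q[1] - G[0, 1] * Q[0]) / det,
            ]
        )

    return rhs


def integrate_pair(
    tables: PairTables,
    state0=(0.0, 0.0),
    n_cycles: float = 10.0,
    driving: Optional[DrivingForce] = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    t_eval=None,
):
    """Integrate the coupled-phase dynamics of the pair.

    At each step the 2x2 force balance is solved for (phidot_1, phidot_2);
    with zero cross-friction both phases advance at exactly omega0.
    Returns the solve_ivp solution object (phases unwrapped).
    """
    if driving is None:
        driving = pair_driving_force(tables)
    w0 = tables.config.omega0
    horizon = n_cycles * TWO_PI / w0 * 1.5
    mean0 = 0.5 * (state0[0] + state0[1])
    target = mean0 + n_cycles * TWO_PI

    def done(t, y):
        return 0.5 * (y[0] + y[1]) - target

    done.terminal = True
    done.direction = 1
    sol = solve_ivp(
        _pair_rhs(tables, driving),
        (0.0, horizon),
        np.asarray(state0, dtype=float),
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=done,
        t_eval=t_eval,
    )
    if not sol.success:
        raise NumericalError(f"pair integration failed: {sol.message}")
    return sol


def lyapunov_exponent(
    tables: PairTables,
    delta0: float = 1e-3,
    driving: Optional[DrivingForce] = None,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> float:
    """One-cycle Lyapunov exponent of the in-phase synchronized state.

    Integrates from phi_1(0) = -delta0/2, phi_2(0) = +delta0/2 until the
    mean phase completes one cycle (mean phase = 2 pi, event detection on
    dense output) and returns ``lambda = log |delta_1 / delta_0|``:
    negative iff in-phase beating is linearly stable.
    """
    if delta0 == 0:
        raise ConfigError("delta0 must be nonzero")
    if abs(delta0) > 0.1:
        warnings.warn("delta0 outside the linear regime; use |delta0| << 1")
    sol = integrate_pair(
        tables,
        state0=(-0.5 * delta0, 0.5 * delta0),
        n_cycles=1.0,
        driving=driving,
        rtol=rtol,
        atol=atol,
    )
    if len(sol.t_events[0]) == 0:
        raise NumericalError("mean phase did not complete a full cycle")
    yT = sol.y_events[0][0]
    delta1 = yT[1] - yT[0]
    if abs(delta1) > 0.1:
        warnings.warn(
            "perturbation left the linear regime during the cycle; "
            "shrink delta0"
        )
    return float(np.log(abs(delta1 / delta0)))


@dataclass
class SteadyStateResult:
    """Attractors of the pair dynamics and basin membership of the probes."""

    attractors: np.ndarray          # distinct steady-state delta* values
    initial_deltas: np.ndarray      # probe initial conditions
    final_deltas: np.ndarray        # converged (or last) delta per probe
    converged: np.ndarray           # bool per probe
    basin: np.ndarray               # attractor index per probe (-1: none)
    cycles_used: np.ndarray


def steady_state_phase_difference(
    tables: PairTables,
    initial_deltas: Optional[Sequence[float]] = None,
    max_cycles: int = 200,
    conv_tol: float = 1e-4,
    cluster_tol: float = 0.05,
    driving: Optional[DrivingForce] = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SteadyStateResult:
    """Steady-state phase differences delta* from a fan of initial conditions.

    delta is sampled stroboscopically at mean-phase multiples of 2*pi (the
    within-cycle oscillation of delta(t) is not an attractor property).
    A probe converges when successive samples differ by < ``conv_tol`` after
    having moved from its initial value (a probe that never moves cannot be
    distinguished from neutral drift and is flagged non-converged);
    converged values are clustered to ``cluster_tol`` into attractors.
    """
    if initial_deltas is None:
        initial_deltas = wrap_phase_difference(
            (np.arange(8) + 1) * TWO_PI / 8.0 - np.pi
        )
    initial_deltas = np.asarray(initial_deltas, dtype=float)
    if driving is None:
        driving = pair_driving_force(tables)
    rhs = _pair_rhs(tables, driving)
    w0 = tables.config.omega0

    finals, conv, cycles = [], [], []
    for d0 in initial_deltas:
        y = np.array([-0.5 * d0, 0.5 * d0])
        mean_target = 0.5 * (y[0] + y[1])
        prev = wrap_phase_difference(y[1] - y[0])
        initial = prev
        moved = False
        ok = False
        k = 0
        for k in range(1, max_cycles + 1):
            mean_target += TWO_PI

            def done(t, yy, target=mean_target):
                return 0.5 * (yy[0] + yy[1]) - target

            done.terminal = True
            done.direction = 1
            sol = solve_ivp(
                rhs,
                (0.0, 1.5 * TWO_PI / w0),
                y,
                method="RK45",
                rtol=rtol,
                atol=atol,
                events=done,
            )
            if not sol.success or len(sol.t_events[0]) == 0:
                break
            y = sol.y_events[0][0]
            cur = wrap_phase_difference(y[1] - y[0])
            if abs(wrap_phase_difference(cur - initial)) > conv_tol:
                moved = True
            if moved and abs(wrap_phase_difference(cur - prev)) < conv_tol:
                ok = True
                prev = cur
                break
            prev = cur
        finals.append(float(prev))
        conv.append(ok)
        cycles.append(k)

    finals = np.asarray(finals)
    conv = np.asarray(conv)
    attractors: list[float] = []
    basin = np.full(len(finals), -1)
    for i, (d, c) in enumerate(zip(finals, conv)):
        if not c:
            continue
        for j, a in enumerate(attractors):
            if abs(wrap_phase_difference(d - a)) < cluster_tol:
                basin[i] = j
                break
        else:
            attractors.append(d)
            basin[i] = len(attractors) - 1
    return SteadyStateResult(
        attractors=np.asarray(attractors),
        initial_deltas=initial_deltas,
        final_deltas=finals,
        converged=conv,
        basin=basin,
        cycles_used=np.asarray(cycles),
    )


# --------------------------------------------------------------------------
# distance / direction scans and far-field fits
# --------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Distance/direction scan of coupling strength and synchronization."""

    d_values: np.ndarray
    psi_values: np.ndarray
    gamma12_norm: np.ndarray   # (n_d, n_psi)
    lyapunov: np.ndarray       # (n_d, n_psi)
    gamma12_exponent: np.ndarray  # per psi, fitted decay exponent (positive)
    lyapunov_exponent: np.ndarray  # per psi
    tables: dict = field(default_factory=dict)


def _loglog_slope(x, y) -> float:
    return float(np.polyfit(np.log(x), np.log(y), 1)[0])


def scan_and_fit(
    pattern: BeatPattern,
    d_values: Sequence[float],
    psi_values: Sequence[float],
    config: KernelConfig,
    omega0: float = TWO_PI * 32.0,
    m: int = 16,
    n_segments: int = 20,
    delta0: float = 1e-3,
    keep_tables: bool = False,
) -> ScanResult:
    """Scan separations and directions; fit far-field power-law exponents.

    For each (d, psi) the pair tables are built, the torus L2 norm of the
    cross-friction and the one-cycle Lyapunov exponent are computed, and
    the decay exponents are least-squares slopes of log-norm (log |lambda|)
    vs log d.  Near-field distances (d < 1.5 L) are excluded from the fits.
    """
    d_values = np.asarray(sorted(d_values), dtype=float)
    psi_values = np.asarray(psi_values, dtype=float)
    far = d_values >= 1.5 * pattern.length * (1.0 - 1e-9)
    if far.sum() < 2:
        raise ConfigError("need at least 2 far-field distances (d >= 1.5 L)")
    if not far.all():
        warnings.warn(
            f"excluding {np.sum(~far)} near-field distance(s) (d < 1.5 L) "
            "from the power-law fits"
        )
    norms = np.empty((d_values.size, psi_values.size))
    lams = np.empty_like(norms)
    kept = {}
    for j, psi in enumerate(psi_values):
        for i, d in enumerate(d_values):
            pc = CiliaPairConfig(
                d=d, psi=psi, omega0=omega0, n_segments=n_segments
            )
            tab = pair_tables(pattern, pc, config, m=m)
            norms[i, j] = tab.gamma12_l2_norm()
            lams[i, j] = lyapunov_exponent(tab, delta0=delta0)
            if keep_tables:
                kept[(float(d), float(psi))] = tab
    g_exp = np.array(
        [-_loglog_slope(d_values[far], norms[far, j]) for j in range(psi_values.size)]
    )
    l_exp = np.array(
        [
            -_loglog_slope(d_values[far], np.abs(lams[far, j]))
            for j in range(psi_values.size)
        ]
    )
    return ScanResult(
        d_values=d_values,
        psi_values=psi_values,
        gamma12_norm=norms,
        lyapunov=lams,
        gamma12_exponent=g_exp,
        lyapunov_exponent=l_exp,
        tables=kept,
    )


def wall_parallel_decay_exponent(
    height: float = 5e-6,
    viscosity: float = 1e-3,
    span=(10.0, 100.0),
    n_points: int = 20,
) -> float:
    """Decay exponent of the wall-parallel point-force far field.

    Evaluates the half-space (Blake) kernel for a unit force parallel to the
    wall at height h, at field points at the same height and lateral
    distances spanning ``span`` (in units of h) along the force direction,
    and returns the negated log-log slope of the flow speed (the classic
    result is 3).
    """
    cfg = KernelConfig(viscosity=viscosity, domain=Domain.HALF_SPACE_WALL)
    d = np.geomspace(span[0] * height, span[1] * height, n_points)
    fld = np.column_stack([d, np.zeros_like(d), np.full_like(d, height)])
    G = mobility_tensor(fld, np.array([[0.0, 0.0, height]]), np.array([0.0]), cfg)
    u = G[:, 0] @ np.array([1.0, 0.0, 0.0])
    mag = np.linalg.norm(u, axis=1)
    return -_loglog_slope(d, mag)
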