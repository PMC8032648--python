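"""Synthetic beat pattern, cilium models, pair coupling and synchronization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagstokes import (
    BeatPattern,
    CiliaPairConfig,
    GeometryError,
    KernelConfig,
    cilia_pair_model,
    cilium_shape_model,
    integrate_pair,
    lyapunov_exponent,
    pair_driving_force,
    pair_tables,
    scan_and_fit,
    single_cilium_table,
    steady_state_phase_difference,
    synthetic_beat_pattern,
    velocity_basis,
    wall_parallel_decay_exponent,
    wrap_phase_difference,
)
from lagstokes.cilia import PairTables
from lagstokes.tables import FrictionTable

TWO_PI = 2 * np.pi
L = 10e-6


# ------------------------------------------------------------ beat pattern


def test_beat_pattern_regression_geometry(pattern):
    """Frozen geometry of the shipped default pattern: extended, high-tip
    effective stroke; low curled recovery; bounded lateral excursion."""
    phis = np.linspace(0, TWO_PI, 64, endpoint=False)
    tip = np.array([pattern.centerline(p, np.array([L]))[0] for p in phis])
    assert tip[:, 2].max() / L == pytest.approx(0.867, abs=0.01)
    assert tip[:, 2].min() / L == pytest.approx(0.312, abs=0.01)
    assert tip[:, 2].min() < 0.5 * L  # recovery brings the tip below L/2
    assert tip[:, 1].min() > 0.0  # beat envelope tilted into +y half-space
    assert 0.1 * L < np.abs(tip[:, 0]).max() < 0.3 * L  # 3-D excursion


def test_beat_pattern_exact_periodicity(pattern):
    s = np.linspace(L / 20, L, 20)
    np.testing.assert_allclose(
        pattern.centerline(0.37, s), pattern.centerline(0.37 + TWO_PI, s),
        rtol=0, atol=1e-18,
    )


def test_zero_asymmetry_gives_planar_beat():
    planar = synthetic_beat_pattern(asym=0.0)
    s = np.linspace(L / 10, L, 10)
    for phi in (0.0, 1.2, 4.4):
        assert np.abs(planar.centerline(phi, s)[:, 0]).max() == 0.0


def test_wall_penetrating_parameters_rejected():
    with pytest.raises(GeometryError, match="penetrates"):
        BeatPattern(tilt=2.2, sweep=0.9).validate()


# ------------------------------------------------------------ shape models


def test_cilium_model_element_counts(pattern):
    model = cilium_shape_model(pattern, n_segments=20)
    sample = model.generate([1.0])
    assert len(sample) == 20
    assert np.all(sample.points[:, 2] > 0.0)
    pair = cilia_pair_model(pattern, CiliaPairConfig(d=18e-6, n_segments=20))
    assert len(pair.generate([0.5, 1.5])) == 40


def test_finite_difference_basis_matches_analytic_derivative(pattern, cilium_model):
    """w(x_k) from central differences agrees with the analytic
    d(centerline)/d(phi) to O(eps^2)."""
    q = [2.2]
    w_an = velocity_basis(cilium_model, q).w
    w_fd = velocity_basis(cilium_model, q, use_analytic=False).w
    assert np.abs(w_an - w_fd).max() < 1e-8 * np.abs(w_an).max()


# ------------------------------------------------------------------ tables


def test_self_friction_varies_over_the_beat(cilium_table):
    """The effective stroke dissipates more: frozen max/min ratio of the
    shipped pattern's Γ11(phi)."""
    g = cilium_table.values[:, 0, 0]
    assert np.all(g > 0.0)
    assert g.max() / g.min() > 1.5


def test_self_friction_scales_linearly_with_viscosity(pattern, cilium_model):
    t1 = single_cilium_table(cilium_model, KernelConfig(
        viscosity=1e-3, domain="half_space_wall"), m=8)
    t2 = single_cilium_table(cilium_model, KernelConfig(
        viscosity=2e-3, domain="half_space_wall"), m=8)
    np.testing.assert_allclose(t2.values, 2.0 * t1.values, rtol=1e-12)


def test_pair_tables_symmetry_and_self_approximation(small_pair_tables):
    v = small_pair_tables.pair2d.values
    asym = np.abs(v[:, :, 0, 1] - v[:, :, 1, 0]).max()
    assert asym / np.abs(v[:, :, 0, 1]).max() < 1e-4
    # self-friction is virtually independent of the other cilium's phase
    assert small_pair_tables.self_approx_error < 0.05


def test_cross_friction_decays_with_distance(pattern, wall_cfg):
    norms = []
    for d in (18e-6, 36e-6):
        tab = pair_tables(
            pattern, CiliaPairConfig(d=d, n_segments=12), wall_cfg, m=8
        )
        norms.append(tab.gamma12_l2_norm())
    assert norms[1] < 0.3 * norms[0]


def test_intersecting_cilia_rejected(pattern, wall_cfg):
    with pytest.raises(GeometryError, match="intersect"):
        pair_tables(
            pattern, CiliaPairConfig(d=0.15e-6, n_segments=12), wall_cfg, m=8
        )


# ---------------------------------------------------------------- dynamics


def _decoupled(tables: PairTables) -> PairTables:
    """Copy of the pair tables with the cross-friction zeroed."""
    v = tables.pair2d.values.copy()
    v[:, :, 0, 1] = v[:, :, 1, 0] = 0.0
    pair2d = FrictionTable(
        grids=tables.pair2d.grids, values=v, periodic=(True, True)
    )
    return PairTables(single=tables.single, pair2d=pair2d, config=tables.config)


def test_zero_coupling_gives_free_running_phases(small_pair_tables):
    tables = _decoupled(small_pair_tables)
    w0 = tables.config.omega0
    sol = integrate_pair(tables, state0=(0.3, 1.7), n_cycles=3)
    T = sol.t_events[0][0]
    yT = sol.y_events[0][0]
    np.testing.assert_allclose(yT, np.array([0.3, 1.7]) + w0 * T, rtol=1e-9)
    assert lyapunov_exponent(tables) == pytest.approx(0.0, abs=1e-9)


def test_in_phase_manifold_is_invariant(small_pair_tables):
    """delta(0) = 0 implies delta(t) stays below 1e-8 over 50 cycles."""
    sol = integrate_pair(small_pair_tables, state0=(0.0, 0.0), n_cycles=50)
    delta = sol.y[1] - sol.y[0]
    assert np.abs(delta).max() < 1e-8


def test_exchange_symmetry_of_identical_cilia(
    pattern, wall_cfg, small_pair_cfg, small_pair_tables
):
    """Swapping the two identical cilia maps the system onto the
    point-reflected geometry: the trajectory with swapped initial phases
    on the psi + pi tables is the label-swapped original trajectory."""
    mirrored = pair_tables(
        pattern,
        CiliaPairConfig(
            d=small_pair_cfg.d, psi=small_pair_cfg.psi + np.pi, n_segments=12
        ),
        wall_cfg, m=8, m_single=16,
    )
    sol_a = integrate_pair(small_pair_tables, state0=(0.2, 1.1), n_cycles=2)
    sol_b = integrate_pair(mirrored, state0=(1.1, 0.2), n_cycles=2)
    T = min(sol_a.t[-1], sol_b.t[-1])
    ts = np.linspace(0, T, 40)
    np.testing.assert_allclose(
        sol_a.sol(ts), sol_b.sol(ts)[::-1], rtol=1e-6, atol=1e-7
    )


def test_lyapunov_is_linear_in_perturbation_size(small_pair_tables):
    lam1 = lyapunov_exponent(small_pair_tables, delta0=1e-3)
    lam2 = lyapunov_exponent(small_pair_tables, delta0=1e-4)
    assert lam1 == pytest.approx(lam2, rel=0.01)


def test_lyapunov_point_reflection_symmetry(pattern, wall_cfg, small_pair_cfg):
    """Swapping the two cilia (psi -> psi + pi) leaves lambda unchanged."""
    lam = {}
    for psi in (small_pair_cfg.psi, small_pair_cfg.psi + np.pi):
        tab = pair_tables(
            pattern,
            CiliaPairConfig(d=small_pair_cfg.d, psi=psi, n_segments=12),
            wall_cfg, m=8, m_single=16,
        )
        lam[psi] = lyapunov_exponent(tab)
    vals = list(lam.values())
    assert vals[0] == pytest.approx(vals[1], rel=1e-3, abs=1e-8)


def test_steady_state_dichotomy_matches_lyapunov_sign(pattern, wall_cfg):
    """lambda < 0 directions settle to delta* = 0; lambda > 0 directions
    settle to anti-phase delta* ~ pi."""
    # directions chosen from the shipped pattern's stability map
    stable = pair_tables(
        pattern, CiliaPairConfig(d=18e-6, psi=11 * np.pi / 6, n_segments=12),
        wall_cfg, m=8, m_single=16,
    )
    unstable = pair_tables(
        pattern, CiliaPairConfig(d=18e-6, psi=np.pi / 3, n_segments=12),
        wall_cfg, m=8, m_single=16,
    )
    lam_s, lam_u = lyapunov_exponent(stable), lyapunov_exponent(unstable)
    assert lam_s < 0 < lam_u

    res_s = steady_state_phase_difference(
        stable, initial_deltas=[0.4], max_cycles=400
    )
    assert abs(res_s.final_deltas[0]) < 0.05

    res_u = steady_state_phase_difference(
        unstable, initial_deltas=[0.4], max_cycles=600
    )
    assert abs(abs(res_u.final_deltas[0]) - np.pi) < 0.3


def test_neutral_pair_is_flagged_unconverged(small_pair_tables):
    tables = _decoupled(small_pair_tables)
    res = steady_state_phase_difference(
        tables, initial_deltas=[0.8], max_cycles=5
    )
    assert not res.converged[0]
    assert res.final_deltas[0] == pytest.approx(0.8, abs=1e-6)


# -------------------------------------------------------------------- scans


def test_scan_excludes_near_field_with_warning(pattern, wall_cfg):
    with pytest.warns(UserWarning, match="near-field"):
        res = scan_and_fit(
            pattern, [10e-6, 20e-6, 30e-6, 45e-6], [np.pi / 3], wall_cfg,
            m=8, n_segments=10,
        )
    assert np.all(np.diff(res.gamma12_norm[:, 0]) < 0)  # monotone decay


def test_kernel_level_decay_exponent_is_three():
    assert wall_parallel_decay_exponent() == pytest.approx(3.0, abs=0.05)


# ------------------------------------------------------------------ helpers


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-50, 50, allow_nan=False))
def test_wrap_phase_difference_properties(x):
    w = float(wrap_phase_difference(x))
    assert -np.pi < w <= np.pi
    assert np.cos(w) == pytest.approx(np.cos(x), abs=1e-9)
    assert np.sin(w) == pytest.approx(np.sin(x), abs=1e-9)
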