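"""Stokes kernels, resistance solve, and their physical invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagstokes import (
    ConfigError,
    DomainError,
    KernelConfig,
    NumericalError,
    ResistanceSolver,
    ShapeError,
    SurfaceSample,
    induced_flow,
    mobility_kernel,
    mobility_tensor,
    solve_traction,
    sphere_sample,
    total_force_torque,
)

MU = 1e-3
A = 1e-6
STOKES_DRAG = 6 * np.pi * MU * A


# ----------------------------------------------------------------- kernels


def test_oseen_tensor_closed_form(free_cfg):
    """Free-space Stokeslet: (I + rr)/(8 pi mu r): xx/yy ratio is 2."""
    r = 3e-6
    G = mobility_kernel(np.zeros(3), np.array([r, 0, 0]), free_cfg)
    assert G[0, 0] / G[1, 1] == pytest.approx(2.0, rel=1e-12)
    assert G[0, 0] == pytest.approx(2.0 / (8 * np.pi * MU * r), rel=1e-12)
    assert np.abs(G - np.diag(np.diag(G))).max() == 0.0


def test_blake_tensor_vanishes_on_wall(wall_cfg):
    """Image-system cancellation: zero flow tensor for field points at z=0."""
    src = np.array([[0.4e-6, -0.7e-6, 2.3e-6]])
    rng = np.random.default_rng(1)
    pts = np.column_stack(
        [rng.uniform(-20, 20, 100), rng.uniform(-20, 20, 100), np.zeros(100)]
    ) * 1e-6
    G = mobility_tensor(pts, src, np.array([0.0]), wall_cfg)
    near = mobility_tensor(src + [[1e-6, 0, 0]], src, np.array([0.0]), wall_cfg)
    assert np.abs(G).max() < 1e-10 * np.abs(near).max()


@pytest.mark.parametrize("domain", ["free_space", "half_space_wall"])
def test_kernel_reciprocity(domain):
    """G(a, b) equals G(b, a)^T componentwise (Lorentz reciprocity)."""
    cfg = KernelConfig(viscosity=MU, domain=domain, regularization=0.1e-6)
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.uniform([-5, -5, 0.5], [5, 5, 8]) * 1e-6
        b = rng.uniform([-5, -5, 0.5], [5, 5, 8]) * 1e-6
        Gab = mobility_kernel(a, b, cfg)
        Gba = mobility_kernel(b, a, cfg)
        np.testing.assert_allclose(Gab, Gba.T, rtol=0, atol=1e-10 * np.abs(Gab).max())


def test_blake_constant_height_decay_is_cubic(wall_cfg):
    """Wall-parallel force, equal heights: flow ~ 1/d^3 over d in [10h, 100h]."""
    h = 1e-6
    d = np.geomspace(10 * h, 100 * h, 25)
    fld = np.column_stack([d, np.zeros_like(d), np.full_like(d, h)])
    G = mobility_tensor(fld, np.array([[0, 0, h]]), np.array([0.0]), wall_cfg)
    mag = np.linalg.norm(G[:, 0] @ np.array([1.0, 0, 0]), axis=1)
    slope = np.polyfit(np.log(d), np.log(mag), 1)[0]
    assert -slope == pytest.approx(3.0, abs=0.05)


def test_singular_kernel_at_source_rejected(free_cfg):
    with pytest.raises(DomainError):
        mobility_kernel(np.zeros(3), np.zeros(3), free_cfg)


def test_wall_penetrating_source_rejected(wall_cfg):
    with pytest.raises(DomainError):
        mobility_tensor(
            np.array([[0, 0, 1e-6]]), np.array([[0, 0, -1e-6]]),
            np.array([0.1e-6]), wall_cfg,
        )


def test_nonpositive_viscosity_rejected():
    with pytest.raises(ConfigError):
        KernelConfig(viscosity=0.0)


# ------------------------------------------------------------ induced flow


def test_induced_flow_zero_and_superposition(free_cfg, sphere500):
    rng = np.random.default_rng(3)
    fld = rng.uniform(-3, 3, (10, 3)) * 1e-6 + [0, 0, 5e-6]
    zero = induced_flow(sphere500, np.zeros((500, 3)), fld, free_cfg)
    assert np.all(zero == 0.0)
    f1 = rng.normal(size=(500, 3))
    f2 = rng.normal(size=(500, 3))
    u12 = induced_flow(sphere500, f1 + f2, fld, free_cfg)
    u1 = induced_flow(sphere500, f1, fld, free_cfg)
    u2 = induced_flow(sphere500, f2, fld, free_cfg)
    np.testing.assert_allclose(u12, u1 + u2, rtol=1e-12)


def test_noslip_wall_for_arbitrary_force_distribution(wall_cfg):
    """Any force distribution: flow on the wall vanishes (singular kernels)."""
    rng = np.random.default_rng(11)
    pts = rng.uniform([-2, -2, 1], [2, 2, 6], (30, 3)) * 1e-6
    sample = SurfaceSample(pts, np.full(30, 1e-13), np.full(30, 1e-30))
    f = rng.normal(size=(30, 3))
    wall_pts = np.column_stack(
        [rng.uniform(-30, 30, 120), rng.uniform(-30, 30, 120), np.zeros(120)]
    ) * 1e-6
    u_wall = induced_flow(sample, f, wall_pts, wall_cfg)
    probe = pts + np.array([3e-6, 0, 0])
    u_ref = induced_flow(sample, f, probe, wall_cfg)
    assert np.abs(u_wall).max() < 1e-10 * np.abs(u_ref).max()


def test_induced_flow_shape_mismatch(free_cfg, sphere500):
    with pytest.raises(ShapeError):
        induced_flow(sphere500, np.zeros((10, 3)), np.zeros((2, 3)), free_cfg)


# -------------------------------------------------------- resistance solve


def test_traction_linearity_and_residual(free_cfg, sphere500):
    """Resistance solve is linear; induced flow reproduces the velocities."""
    rng = np.random.default_rng(5)
    solver = ResistanceSolver(sphere500, free_cfg)
    v1 = rng.normal(size=(500, 3)) * 1e-6
    v2 = rng.normal(size=(500, 3)) * 1e-6
    f1, f2, f12 = solver.solve(v1), solver.solve(v2), solver.solve(v1 + v2)
    np.testing.assert_allclose(f12, f1 + f2, rtol=1e-8, atol=np.abs(f1).max() * 1e-10)
    assert np.all(solver.solve(np.zeros((500, 3))) == 0.0)
    u = induced_flow(sphere500, f1, sphere500.points, free_cfg)
    assert np.linalg.norm(u - v1) / np.linalg.norm(v1) < 1e-8


def test_sphere_drag_matches_stokes_law(free_cfg, sphere500):
    """Rigid translation of a sphere: total force within 5% of 6 pi mu a v."""
    v = 1e-6
    f = solve_traction(sphere500, np.tile([v, 0, 0], (500, 1)), free_cfg)
    F, M = total_force_torque(sphere500, f, (0, 0, 0))
    assert F[0] == pytest.approx(STOKES_DRAG * v, rel=0.05)
    assert np.abs(F[1:]).max() < 0.01 * F[0]
    assert np.abs(M).max() < 0.01 * F[0] * A


def test_sphere_drag_converges_monotonically(free_cfg):
    """Drag error decreases monotonically over a doubling element sequence."""
    errs = []
    for n in (125, 250, 500):
        s = sphere_sample(A, n)
        f = solve_traction(s, np.tile([1e-6, 0, 0], (n, 1)), free_cfg)
        F, _ = total_force_torque(s, f)
        errs.append(abs(F[0] - STOKES_DRAG * 1e-6) / (STOKES_DRAG * 1e-6))
    assert errs[0] > errs[1] > errs[2]


def test_coincident_points_raise_conditioning_error(free_cfg):
    pts = np.array([[0, 0, 0], [0, 0, 0], [1e-6, 0, 0]], dtype=float)
    sample = SurfaceSample(pts, np.full(3, 1e-13), np.full(3, 1e-7))
    with pytest.raises(NumericalError, match="ill-conditioned"):
        ResistanceSolver(sample, free_cfg)


# ------------------------------------------------------- force and torque


def test_total_force_torque_trivial_cases(sphere500):
    F, M = total_force_torque(sphere500, np.zeros((500, 3)))
    assert np.all(F == 0) and np.all(M == 0)
    # uniform traction on a mirror-symmetric sample, reference at centroid
    uniform = np.tile([0, 0, 1.0], (500, 1))
    _, M = total_force_torque(sphere500, uniform, sphere500.points.mean(axis=0))
    scale = sphere500.areas.sum() * A
    assert np.abs(M).max() < 1e-8 * scale


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    v=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
    w=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
)
def test_rigid_motion_dissipation_nonnegative(v, w):
    """Energy: sum v.f A >= 0 for any rigid motion (dissipation >= 0)."""
    cfg = KernelConfig(viscosity=MU)
    s = sphere_sample(A, 100)
    vel = (np.asarray(v) * 1e-6) + np.cross(np.asarray(w), s.points)
    f = solve_traction(s, vel, cfg)
    power = np.einsum("ki,ki,k->", vel, f, s.areas)
    assert power >= -1e-25


# ------------------------------------------------------------- sample I/O


def test_surface_sample_roundtrip(tmp_path, sphere500):
    import h5py

    csv = tmp_path / "s.csv"
    sphere500.to_csv(csv)
    back = SurfaceSample.from_csv(csv)
    np.testing.assert_allclose(back.points, sphere500.points, rtol=1e-15)
    np.testing.assert_allclose(back.areas, sphere500.areas, rtol=1e-15)

    h5 = tmp_path / "s.h5"
    with h5py.File(h5, "w") as f:
        sphere500.to_hdf5(f.create_group("sample"))
    with h5py.File(h5, "r") as f:
        back2 = SurfaceSample.from_hdf5(f["sample"])
    np.testing.assert_array_equal(back2.points, sphere500.points)
    np.testing.assert_array_equal(back2.element_radius, sphere500.element_radius)
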