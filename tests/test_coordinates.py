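"""Velocity/force bases, the friction matrix Γ, and its invariants."""

import numpy as np
import pytest

from lagstokes import (
    CoordSpec,
    KernelConfig,
    ResistanceSolver,
    ShapeModel,
    SurfaceSample,
    dissipation_rate,
    force_basis,
    friction_matrix,
    generalized_forces,
    solve_traction,
    sphere_sample,
    total_force_torque,
    velocity_basis,
)
from lagstokes.coordinates import FrictionMatrix

MU = 1e-3
A = 1e-6


def _blob_cloud(pts):
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    return SurfaceSample(pts, np.full(n, 1e-13), np.full(n, 1e-7))


def _poly_model(power):
    """Analytic test shape x_k(q) = x_k(0) + q^power c (Taylor oracle)."""
    base = np.array([[0, 0, 1e-6], [1e-6, 0, 1e-6], [0, 1e-6, 2e-6]])
    c = np.array([1e-6, -2e-6, 0.5e-6])

    def generate(q):
        return _blob_cloud(base + q[0] ** power * c)

    return ShapeModel(
        name=f"poly{power}", n_coords=1, generate=generate,
        coords=(CoordSpec(kind="linear", unit="1"),),
    ), c


def test_central_difference_matches_taylor_oracle():
    """Central differencing: exact for x0 + q^2 c (derivative 2qc); for a
    cubic shape the O(eps^2) error shrinks 4x when eps is halved."""
    quad, c = _poly_model(2)
    w = velocity_basis(quad, [1.0], fd_step=1e-3).w[0]
    np.testing.assert_allclose(w, np.tile(2.0 * c, (3, 1)), rtol=1e-9)

    cubic, c = _poly_model(3)  # central difference error is exactly eps^2 * c
    errs = []
    for eps in (1e-2, 5e-3):
        w = velocity_basis(cubic, [1.0], fd_step=eps).w[0]
        errs.append(np.abs(w - 3.0 * c).max())
    assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.05)


def test_static_coordinate_gives_zero_basis():
    base = np.array([[0, 0, 1e-6], [1e-6, 0, 1e-6]])
    model = ShapeModel(
        name="static", n_coords=1,
        generate=lambda q: _blob_cloud(base),
        coords=(CoordSpec(kind="linear"),),
    )
    assert np.all(velocity_basis(model, [0.3]).w == 0.0)


def test_rigid_translation_coordinate_is_exact_unit_field():
    base = np.array([[0, 0, 1e-6], [1e-6, 0, 2e-6]])
    model = ShapeModel(
        name="slide", n_coords=1,
        generate=lambda q: _blob_cloud(base + q[0] * np.array([1.0, 0, 0])),
        coords=(CoordSpec(kind="rigid_translation", axis=(1, 0, 0), unit="m"),),
    )
    w = velocity_basis(model, [0.7]).w[0]
    assert np.all(w == np.array([1.0, 0.0, 0.0]))


def test_force_basis_is_normalization_independent(free_cfg, sphere500):
    """g_j = traction(alpha w_j)/alpha is the same for alpha and 10 alpha."""
    rng = np.random.default_rng(2)
    w = rng.normal(size=(1, 500, 3))
    solver = ResistanceSolver(sphere500, free_cfg)
    g1 = solver.solve(w[0])
    g10 = solver.solve(10.0 * w[0]) / 10.0
    np.testing.assert_allclose(g1, g10, rtol=1e-9)


def sphere_translation_model(n=400):
    s0 = sphere_sample(A, n)

    def generate(q):
        return s0.translated(q)

    return ShapeModel(
        name="sphere3", n_coords=3, generate=generate,
        coords=tuple(
            CoordSpec(kind="rigid_translation", axis=tuple(np.eye(3)[i]), unit="m")
            for i in range(3)
        ),
    )


def test_sphere_friction_matrix_is_stokes_drag_identity(free_cfg):
    """3 translation coordinates of a sphere: Γ = 6 pi mu a I within 5%."""
    model = sphere_translation_model()
    gam = friction_matrix(model, np.zeros(3), free_cfg)
    drag = 6 * np.pi * MU * A
    np.testing.assert_allclose(gam.matrix, drag * np.eye(3), atol=0.05 * drag)
    assert gam.asymmetry() < 1e-10


def test_friction_matrix_symmetric_positive_definite(small_pair_tables):
    """Two-cilium Γ at every grid node: symmetric (reciprocity) and PD."""
    vals = small_pair_tables.pair2d.values
    scale = np.abs(vals).max()
    asym = np.abs(vals - np.swapaxes(vals, -1, -2)).max()
    assert asym / scale < 1e-6
    eigs = np.linalg.eigvalsh(0.5 * (vals + np.swapaxes(vals, -1, -2)))
    assert eigs.min() > 0.0


def test_single_cilium_friction_positive_at_all_phases(cilium_table):
    assert np.all(cilium_table.values[:, 0, 0] > 0.0)


def test_generalized_forces_basics():
    P = generalized_forces(np.diag([2.0, 3.0]), [1.0, 0.0])
    np.testing.assert_allclose(P, [2.0, 0.0])
    assert np.all(generalized_forces(np.eye(2), np.zeros(2)) == 0.0)


def test_rigid_generalized_forces_match_surface_integrals(free_cfg):
    """P of rigid coordinates equals components of total force/torque."""
    from lagstokes import MaterialFrame, grand_friction_matrix, rigid_velocity_field, RigidVelocity

    s = sphere_sample(A, 300, center=(0.5e-6, 0, 0))
    frame = MaterialFrame.identity()
    gam = grand_friction_matrix(s, frame, free_cfg)
    rng = np.random.default_rng(4)
    qdot = rng.normal(size=6)
    P = generalized_forces(gam, qdot)
    rv = RigidVelocity(v=qdot[:3], omega=qdot[3:])
    v = rigid_velocity_field(s, frame, rv)
    f = solve_traction(s, v, free_cfg)
    F, M = total_force_torque(s, f, frame.x0)
    np.testing.assert_allclose(P[:3], F, rtol=1e-6)
    np.testing.assert_allclose(P[3:], M, rtol=1e-6)


def test_dissipation_rate_identities(free_cfg, sphere500):
    """R = qdot.Γ.qdot equals the direct surface quadrature of v.f."""
    model = sphere_translation_model(n=500)
    gam = friction_matrix(model, np.zeros(3), free_cfg)
    qdot = np.array([1e-6, -2e-6, 0.5e-6])
    R = dissipation_rate(gam, qdot)
    # direct surface integral with the same discretization
    v = np.tile(qdot, (500, 1))
    f = solve_traction(model.generate(np.zeros(3)), v, free_cfg)
    R_direct = np.einsum("ki,ki,k->", v, f, model.generate(np.zeros(3)).areas)
    assert R == pytest.approx(R_direct, rel=1e-8)
    assert R == pytest.approx(generalized_forces(gam, qdot) @ qdot, rel=1e-12)
    assert dissipation_rate(gam, 2.0 * qdot) == pytest.approx(4.0 * R, rel=1e-12)
    assert dissipation_rate(gam, np.zeros(3)) == 0.0


def test_negative_definite_matrix_rejected():
    with pytest.raises(Exception):
        dissipation_rate(-np.eye(2), np.ones(2))


def test_coordinate_rescaling_rescales_rows_and_columns(wall_cfg, cilium_model):
    """q_i -> c q_i rescales row i and column i of Γ by 1/c each."""
    c = 2.0
    inner = cilium_model

    def generate(q):
        return inner.generate([c * q[0]])

    def analytic(q):
        return c * inner.analytic_basis([c * q[0]])

    scaled = ShapeModel(
        name="scaled", n_coords=1, generate=generate,
        coords=(CoordSpec(kind="linear"),), analytic_basis=analytic,
    )
    q0 = 0.9
    g_orig = friction_matrix(inner, [q0], wall_cfg).matrix
    g_scaled = friction_matrix(scaled, [q0 / c], wall_cfg).matrix
    np.testing.assert_allclose(g_scaled, c**2 * g_orig, rtol=1e-8)


def test_friction_matrix_container_validation():
    with pytest.raises(Exception):
        FrictionMatrix(matrix=np.ones((2, 3)))
    fm = FrictionMatrix(matrix=np.array([[2.0, 1.0], [1.0, 2.0]]))
    assert fm.asymmetry() == 0.0
    assert fm.eigenvalues().min() == pytest.approx(1.0)


def test_friction_matrix_csv_roundtrip(tmp_path):
    fm = FrictionMatrix(
        matrix=np.array([[2.0, 0.5], [0.5, 3.0]]),
        units=("rad", "rad"), coord_names=("phi1", "phi2"),
    )
    path = tmp_path / "gamma.csv"
    fm.to_csv(path)
    assert "phi1[rad]" in path.read_text()
    back = FrictionMatrix.from_csv(path)
    np.testing.assert_allclose(back.matrix, fm.matrix, rtol=1e-15)
    assert back.coord_names == fm.coord_names
    assert back.units == fm.units
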