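"""Zero-Reynolds-number hydrodynamic kernels and the resistance solve.

Implements the method of regularized Stokeslets (Cortez blob) in free space
and in the half space above a plane no-slip wall (Blake image system), and
the collocation resistance solve mapping prescribed surface velocities to
traction densities.

Kernel conventions
------------------
``mobility_kernel(source, field)`` returns the 3x3 tensor ``G`` such that a
point force ``F`` at ``source`` induces flow ``u = G @ F`` at ``field``.  The
regularized free-space Stokeslet for the blob

.. math:: \\psi_\\varepsilon(r) = \\frac{15 \\varepsilon^4}
          {8 \\pi (r^2+\\varepsilon^2)^{7/2}}

is

.. math:: 8\\pi\\mu\\, G_{ij} = \\delta_{ij}\\frac{r^2 + 2\\varepsilon^2}
          {(r^2+\\varepsilon^2)^{3/2}} + \\frac{r_i r_j}{(r^2+\\varepsilon^2)^{3/2}}.

For the half space the classical image system (image Stokeslet, Stokeslet
doublet, source doublet) is used; its correction terms are regularized with
the same ``r -> sqrt(r^2 + eps^2)`` substitution.  With ``eps = 0`` the
kernel satisfies u = 0 on the wall exactly; with ``eps > 0`` the on-wall
residual is O(eps^2 / h^2) relative to the flow at source height h.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.linalg

from .errors import ConfigError, DomainError, NumericalError, ShapeError
from .sample import SurfaceSample

__all__ = [
    "Domain",
    "KernelConfig",
    "mobility_kernel",
    "mobility_tensor",
    "induced_flow",
    "ResistanceSolver",
    "solve_traction",
    "total_force_torque",
]


class Domain(str, Enum):
    FREE_SPACE = "free_space"
    HALF_SPACE_WALL = "half_space_wall"


@dataclass(frozen=True)
class KernelConfig:
    """Physical and numerical configuration of the flow kernels.

    Parameters
    ----------
    viscosity
        Dynamic viscosity mu, in Pa s.
    domain
        ``free_space`` or ``half_space_wall`` (no-slip plane fixed at z = 0).
    regularization
        Blob radius in meters used by :func:`mobility_kernel` for single
        point pairs.  In sample-based operations each element uses its own
        ``element_radius`` unless this value overrides it (see
        ``override_element_radius``).
    override_element_radius
        If True, ``regularization`` replaces the per-element blob radii.
    """

    viscosity: float = 1e-3
    domain: Domain = Domain.FREE_SPACE
    regularization: float = 0.0
    override_element_radius: bool = False

    def __post_init__(self):
        if self.viscosity <= 0:
            raise ConfigError(f"viscosity must be > 0, got {self.viscosity}")
        if self.regularization < 0:
            raise ConfigError("regularization (blob radius) must be >= 0")
        object.__setattr__(self, "domain", Domain(self.domain))

    @property
    def is_half_space(self) -> bool:
        return self.domain is Domain.HALF_SPACE_WALL

    def element_eps(self, sample: SurfaceSample) -> np.ndarray:
        """Per-element blob radii to use for ``sample`` under this config."""
        if self.override_element_radius:
            if self.regularization <= 0:
                raise ConfigError(
                    "override_element_radius requires regularization > 0"
                )
            return np.full(len(sample), self.regularization)
        return sample.element_radius


# --------------------------------------------------------------------------
# kernel evaluation (vectorized over field x source point pairs)
# --------------------------------------------------------------------------


def _stokeslet_free(r: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Regularized free-space Stokeslet without the 1/(8 pi mu) prefactor.

    ``r``: (..., 3) displacement field_point - source_point; ``eps``
    broadcastable to ``r[..., 0]``.  Returns (..., 3, 3).
    """
    r2 = np.einsum("...i,...i->...", r, r)
    re2 = r2 + eps**2
    re3 = re2 * np.sqrt(re2)
    out = np.einsum("...i,...j->...ij", r, r) / re3[..., None, None]
    diag = (r2 + 2.0 * eps**2) / re3
    out[..., 0, 0] += diag
    out[..., 1, 1] += diag
    out[..., 2, 2] += diag
    return out


def _blake_correction(R: np.ndarray, h: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Image-system correction beyond the image Stokeslet.

    ``R``: (..., 3) displacement field_point - image_point, ``h`` source
    heights, broadcastable.  Returns (..., 3, 3) tensor ``C_ij`` (velocity
    component i per force component j, without 1/(8 pi mu)) so that the full
    wall kernel is ``S(r) - S(R) + C``.

    C_ij = 2 h M_jl d/dR_l [ h R_i / Re^3 - delta_i3 / Re - R_i R_3 / Re^3 ]
    with M = diag(1, 1, -1) and Re = sqrt(|R|^2 + eps^2).
    """
    R2 = np.einsum("...i,...i->...", R, R)
    Re2 = R2 + eps**2
    Re = np.sqrt(Re2)
    Re3 = Re2 * Re
    Re5 = Re3 * Re2
    R3 = R[..., 2]
    delta = np.eye(3)
    # dphi[..., i, l] = d phi_i / d R_l
    dphi = (
        h[..., None, None] * (delta / Re3[..., None, None]
                              - 3.0 * np.einsum("...i,...l->...il", R, R) / Re5[..., None, None])
        + np.einsum("i,...l->...il", delta[2], R) / Re3[..., None, None]
        - (delta * R3[..., None, None]
           + np.einsum("...i,l->...il", R, delta[2])) / Re3[..., None, None]
        + 3.0 * (R3 / Re5)[..., None, None] * np.einsum("...i,...l->...il", R, R)
    )
    mirror = np.array([1.0, 1.0, -1.0])
    # C_ij = 2 h dphi_il M_lj  (M diagonal)
    return 2.0 * h[..., None, None] * dphi * mirror[None, :]


def mobility_tensor(
    field_points: np.ndarray,
    source_points: np.ndarray,
    eps: np.ndarray,
    config: KernelConfig,
    validate: bool = True,
) -> np.ndarray:
    """Pairwise mobility tensors ``G[m, n]`` (3x3 each): ``u_m = G[m,n] @ F_n``.

    ``eps`` is the per-source blob radius, shape (N,) (zeros allowed for
    singular kernels when field and source points never coincide).
    """
    X = np.atleast_2d(np.asarray(field_points, dtype=float))
    Y = np.atleast_2d(np.asarray(source_points, dtype=float))
    eps = np.broadcast_to(np.asarray(eps, dtype=float), (Y.shape[0],))
    if X.shape[1] != 3 or Y.shape[1] != 3:
        raise ShapeError("points must be (N, 3)")
    if validate and config.is_half_space:
        if np.any(Y[:, 2] <= 0):
            raise DomainError("all source points must lie strictly above the wall z = 0")
        if np.any(X[:, 2] < -1e-300):
            raise DomainError("field points must satisfy z >= 0 in half-space mode")
    r = X[:, None, :] - Y[None, :, :]
    e = eps[None, :]
    G = _stokeslet_free(r, e)
    if config.is_half_space:
        h = Y[:, 2]
        Ystar = Y * np.array([1.0, 1.0, -1.0])
        R = X[:, None, :] - Ystar[None, :, :]
        G = G - _stokeslet_free(R, e) + _blake_correction(
            R, np.broadcast_to(h[None, :], R.shape[:2]), e
        )
    return G / (8.0 * np.pi * config.viscosity)


def mobility_kernel(source, field, config: KernelConfig) -> np.ndarray:
    """3x3 mobility tensor (velocity per unit force) for one source/field pair.

    Uses ``config.regularization`` as the blob radius; ``0`` selects the
    singular kernel (then ``source != field`` is required).
    """
    source = np.asarray(source, dtype=float)
    field = np.asarray(field, dtype=float)
    if config.regularization == 0.0 and np.allclose(source, field):
        raise DomainError("singular kernel evaluated at the source point; "
                          "set regularization > 0")
    G = mobility_tensor(field[None, :], source[None, :],
                        np.array([config.regularization]), config)
    return G[0, 0]


def induced_flow(
    sample: SurfaceSample,
    force_density: np.ndarray,
    field_points: np.ndarray,
    config: KernelConfig,
) -> np.ndarray:
    """Flow velocities at ``field_points`` induced by a surface force density.

    Superposition of (regularized) Stokeslets: each element carries force
    ``force_density_k * A_k``.
    """
    f = np.asarray(force_density, dtype=float)
    if f.shape != (len(sample), 3):
        raise ShapeError(
            f"force_density must be ({len(sample)}, 3), got {f.shape}"
        )
    if config.is_half_space:
        sample.require_above_wall()
    G = mobility_tensor(field_points, sample.points, config.element_eps(sample),
                        config)
    return np.einsum("mnij,nj->mi", G, f * sample.areas[:, None])


# --------------------------------------------------------------------------
# resistance solve
# --------------------------------------------------------------------------


class ResistanceSolver:
    """LU-factorized resistance problem for a fixed sample and kernel config.

    Builds the dense collocation matrix mapping element forces to element
    velocities, factorizes it once, and solves ``velocities -> tractions``
    for arbitrarily many right-hand sides.  Keeps a count of solves for
    cost bookkeeping.
    """

    RCOND_MIN = 1e-13

    def __init__(self, sample: SurfaceSample, config: KernelConfig):
        if len(sample) < 1:
            raise ShapeError("sample must contain at least one element")
        if config.is_half_space:
            sample.require_above_wall()
        self.sample = sample
        self.config = config
        self.n_solves = 0
        n = len(sample)
        G = mobility_tensor(sample.points, sample.points,
                            config.element_eps(sample), config)
        # A[3m+i, 3k+j] = G[m,k,i,j] * area_k : maps traction to velocity
        A = (G * sample.areas[None, :, None, None]).transpose(0, 2, 1, 3)
        self._matrix = A.reshape(3 * n, 3 * n)
        anorm = np.linalg.norm(self._matrix, 1)
        self._lu, self._piv = scipy.linalg.lu_factor(self._matrix)
        rcond, _ = scipy.linalg.lapack.dgecon(self._lu, anorm, norm="1")
        if not np.isfinite(rcond) or rcond < self.RCOND_MIN:
            raise NumericalError(
                f"resistance matrix is ill-conditioned (rcond ~ {rcond:.2e}); "
                "check for coincident collocation points"
            )
        self.rcond = float(rcond)

    def solve(self, velocities: np.ndarray) -> np.ndarray:
        """Traction density (N, 3) reproducing the prescribed velocities."""
        v = np.asarray(velocities, dtype=float)
        single = v.ndim == 2
        if single:
            v = v[None, ...]
        n = len(self.sample)
        if v.shape[1:] != (n, 3):
            raise ShapeError(f"velocities must be ({n}, 3)")
        if not np.all(np.isfinite(v)):
            raise ShapeError("non-finite velocities")
        rhs = v.reshape(v.shape[0], 3 * n).T
        sol = scipy.linalg.lu_solve((self._lu, self._piv), rhs)
        self.n_solves += v.shape[0]
        tractions = sol.T.reshape(v.shape[0], n, 3)
        return tractions[0] if single else tractions


def solve_traction(
    sample: SurfaceSample, velocities: np.ndarray, config: KernelConfig
) -> np.ndarray:
    """One-shot resistance solve; see :class:`ResistanceSolver`."""
    return ResistanceSolver(sample, config).solve(velocities)


def total_force_torque(
    sample: SurfaceSample, traction: np.ndarray, reference_point=(0.0, 0.0, 0.0)
):
    """Total force and torque exerted by the surface on the fluid.

    F = sum_k f_k A_k ; M = sum_k (x_k - x0) x f_k A_k.
    """
    f = np.asarray(traction, dtype=float)
    if f.shape != (len(sample), 3):
        raise ShapeError(f"traction must be ({len(sample)}, 3), got {f.shape}")
    x0 = np.asarray(reference_point, dtype=float)
    fa = f * sample.areas[:, None]
    force = fa.sum(axis=0)
    torque = np.cross(sample.points - x0, fa).sum(axis=0)
    return force, torque
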