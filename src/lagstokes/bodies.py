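"""Built-in rigid and shape-changing bodies: sphere clusters, three-sphere swimmer.

The three-sphere swimmer is the classic minimal linear microswimmer: three
collinear spheres whose two arm lengths change cyclically.  A non-reciprocal
(four-stroke) arm cycle encloses area in shape space and yields a net
displacement per cycle that is a geometric quantity, independent of cycle
duration; a reciprocal (one-armed) stroke yields none.
"""

from __future__ import annotations

from typing import Callable, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .rigid import ShapeProtocol
from .sample import SurfaceSample, merge_samples, sphere_sample

__all__ = [
    "sphere_cluster",
    "three_sphere_sample",
    "three_sphere_stroke",
    "three_sphere_protocol",
    "reciprocal_protocol",
]


def sphere_cluster(
    centers: Sequence, radii, n_per_sphere: int = 200
) -> SurfaceSample:
    """Point-cloud sample of a rigid cluster of spheres."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (centers.shape[0],))
    return merge_samples(
        *[
            sphere_sample(r, n_per_sphere, center=c)
            for c, r in zip(centers, radii)
        ]
    )


def three_sphere_sample(
    a: float, L1: float, L2: float, n_per_sphere: int = 60
) -> Tuple[SurfaceSample, np.ndarray, np.ndarray]:
    """Three collinear spheres along the body x-axis.

    Middle sphere at the body origin, left sphere at -L1, right at +L2
    (arm lengths L1, L2 between neighboring centers).  Returns the sample
    plus the per-element displacement patterns for unit changes of L1 and
    L2 (only the respective outer sphere moves).
    """
    if min(L1, L2) <= 2 * a:
        raise ConfigError("arm lengths must exceed the sphere diameter")
    left = sphere_sample(a, n_per_sphere, center=(-L1, 0.0, 0.0))
    mid = sphere_sample(a, n_per_sphere, center=(0.0, 0.0, 0.0))
    right = sphere_sample(a, n_per_sphere, center=(L2, 0.0, 0.0))
    sample = merge_samples(left, mid, right)
    n = n_per_sphere
    dL1 = np.zeros((3 * n, 3))
    dL1[:n, 0] = -1.0  # growing L1 pushes the left sphere further out
    dL2 = np.zeros((3 * n, 3))
    dL2[2 * n :, 0] = 1.0
    return sample, dL1, dL2


def three_sphere_stroke(
    D: float, u: float, T: float
) -> Callable[[float], Tuple[float, float, float, float]]:
    """Four-stroke square cycle in (L1, L2) shape space, period T.

    Legs (each T/4): L1: D->D-u | L2: D->D-u | L1: D-u->D | L2: D-u->D.
    Returns t -> (L1, L2, dL1/dt, dL2/dt).
    """
    if not (0 < u < D):
        raise ConfigError("stroke amplitude must satisfy 0 < u < D")
    rate = 4.0 * u / T

    def stroke(t: float):
        s = np.mod(t, T) / T
        if s < 0.25:
            f = s / 0.25
            return D - u * f, D, -rate, 0.0
        if s < 0.5:
            f = (s - 0.25) / 0.25
            return D - u, D - u * f, 0.0, -rate
        if s < 0.75:
            f = (s - 0.5) / 0.25
            return D - u + u * f, D - u, rate, 0.0
        f = (s - 0.75) / 0.25
        return D, D - u + u * f, 0.0, rate

    return stroke


def three_sphere_protocol(
    a: float = 1e-6,
    D: float = 10e-6,
    u: float = 4e-6,
    T: float = 1.0,
    n_per_sphere: int = 60,
    reverse: bool = False,
) -> ShapeProtocol:
    """Shape protocol for the four-stroke three-sphere swimmer cycle."""
    stroke = three_sphere_stroke(D, u, T)

    def shape(t: float):
        tt = T - t if reverse else t
        L1, L2, dL1, dL2 = stroke(tt)
        if reverse:
            dL1, dL2 = -dL1, -dL2
        sample, b1, b2 = three_sphere_sample(a, L1, L2, n_per_sphere)
        return sample, dL1 * b1 + dL2 * b2

    return ShapeProtocol(shape=shape, period=T)


def reciprocal_protocol(
    a: float = 1e-6,
    D: float = 10e-6,
    u: float = 4e-6,
    T: float = 1.0,
    n_per_sphere: int = 60,
) -> ShapeProtocol:
    """Reciprocal single-arm stroke: L1 oscillates, L2 fixed (scallop)."""

    def shape(t: float):
        phase = 2.0 * np.pi * t / T
        L1 = D - 0.5 * u * (1.0 - np.cos(phase))
        dL1 = -0.5 * u * np.sin(phase) * 2.0 * np.pi / T
        sample, b1, _ = three_sphere_sample(a, L1, D, n_per_sphere)
        return sample, dL1 * b1

    return ShapeProtocol(shape=shape, period=T)
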