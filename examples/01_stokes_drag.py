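"""Resistance solve on a rigid sphere: recover Stokes' law.

Discretizes a 1 um sphere as a point cloud of regularized Stokeslets,
prescribes a rigid translation, solves for the surface traction and
integrates it to the total drag force, comparing with 6 pi mu a v.
"""

import numpy as np

from lagstokes import (
    KernelConfig, solve_traction, sphere_sample, total_force_torque,
)

mu = 1e-3       # Pa s (water)
a = 1e-6        # sphere radius, m
v = 10e-6       # towing speed, m/s
N = 500

cfg = KernelConfig(viscosity=mu)
sphere = sphere_sample(a, N)
traction = solve_traction(sphere, np.tile([v, 0, 0], (N, 1)), cfg)
F, M = total_force_torque(sphere, traction, (0, 0, 0))
exact = 6 * np.pi * mu * a * v

print(f"computed drag force : {F[0] / 1e-12:8.4f} pN")
print(f"Stokes law 6 pi mu a v: {exact / 1e-12:8.4f} pN")
print(f"relative error      : {abs(F[0] - exact) / exact:.2%}")
print(f"torque (should be ~0): {np.abs(M).max() / (exact * a):.1e} x F a")
# The few-percent error is the blob-discretization error of the N-point
# cloud; it shrinks roughly as 1/sqrt(N).
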