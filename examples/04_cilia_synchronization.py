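"""Hydrodynamic synchronization of two wall-anchored cilia.

Builds pair friction tables at d = 18 um for two separation directions,
computes the one-cycle Lyapunov exponent of the in-phase state (negative:
in-phase synchronization is stable; positive: unstable), and integrates the
coupled phase dynamics to the steady-state phase difference delta*.
Run time ~20 s (reduced table resolution).
"""

import numpy as np

from lagstokes import (
    CiliaPairConfig, KernelConfig, lyapunov_exponent, pair_tables,
    steady_state_phase_difference, synthetic_beat_pattern,
)

wall = KernelConfig(viscosity=1e-3, domain="half_space_wall")
pattern = synthetic_beat_pattern()

for psi_deg in (330.0, 60.0):
    pair = CiliaPairConfig(d=18e-6, psi=np.deg2rad(psi_deg), n_segments=12)
    tables = pair_tables(pattern, pair, wall, m=8, m_single=16)
    lam = lyapunov_exponent(tables)
    ss = steady_state_phase_difference(
        tables, initial_deltas=[0.5], max_cycles=500
    )
    print(f"psi = {psi_deg:5.1f} deg:  lambda = {lam:+.4f}/cycle  ->  "
          f"delta* = {ss.final_deltas[0]:+.3f} rad "
          f"({'in-phase' if lam < 0 else 'anti-phase'} synchronization)")
print("The two cilia lock in phase (delta* = 0) where the in-phase state is "
      "linearly stable,\nand near anti-phase (delta* ~ +/-pi) where it is "
      "unstable; both couplings decay as ~1/d^3.")
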