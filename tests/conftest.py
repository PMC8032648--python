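"""Shared fixtures: kernel configs, small discretizations, cached tables.

Expensive artifacts (friction tables, direction scans) are session-scoped
and sized down (fewer segments, coarser phase grids) relative to the
production defaults; the physics they probe is resolution-independent.
"""

import numpy as np
import pytest

from lagstokes import (
    CiliaPairConfig,
    KernelConfig,
    cilium_shape_model,
    pair_tables,
    single_cilium_table,
    sphere_sample,
    synthetic_beat_pattern,
)

MU = 1e-3  # Pa s, water
A_SPHERE = 1e-6  # m


@pytest.fixture(scope="session")
def free_cfg():
    return KernelConfig(viscosity=MU, domain="free_space")


@pytest.fixture(scope="session")
def wall_cfg():
    return KernelConfig(viscosity=MU, domain="half_space_wall")


@pytest.fixture(scope="session")
def sphere500():
    return sphere_sample(A_SPHERE, 500)


@pytest.fixture(scope="session")
def pattern():
    return synthetic_beat_pattern()


@pytest.fixture(scope="session")
def cilium_model(pattern):
    # 12 segments: cheap but resolves the beat
    return cilium_shape_model(pattern, n_segments=12)


@pytest.fixture(scope="session")
def cilium_table(cilium_model, wall_cfg):
    return single_cilium_table(cilium_model, wall_cfg, m=16)


@pytest.fixture(scope="session")
def small_pair_cfg():
    return CiliaPairConfig(d=18e-6, psi=5 * np.pi / 6, n_segments=12)


@pytest.fixture(scope="session")
def small_pair_tables(pattern, small_pair_cfg, wall_cfg):
    return pair_tables(pattern, small_pair_cfg, wall_cfg, m=8, m_single=16)
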