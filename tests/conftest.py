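"""Shared fixtures: analytic oracles and small synthetic populations.

Everything is generated programmatically; expensive artifacts (optimized
particle systems) are session-scoped so multiple tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from shapecorr.correspond import OptimizerConfig, optimize
from shapecorr.synth import GroupSpec, PopulationSpec, generate_population
from shapecorr.volumes import BinaryVolume, SphereSDF, mask_to_sdf


def digitize_ball(radius: float, spacing: float, margin: int = 4) -> BinaryVolume:
    """Voxelized ball centered on the grid (analytic oracle substrate)."""
    n = int(2 * (radius / spacing + margin) + 1)
    origin = -(n - 1) / 2.0 * spacing
    ax = origin + np.arange(n) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = (xx**2 + yy**2 + zz**2 <= radius**2).astype(np.uint8)
    return BinaryVolume(grid, np.full(3, spacing), np.full(3, origin))


@pytest.fixture(scope="session")
def ball_volume():
    return digitize_ball(radius=5.0, spacing=0.5)


@pytest.fixture(scope="session")
def ball_sdf(ball_volume):
    return mask_to_sdf(ball_volume, smoothing_sigma=0.0)


@pytest.fixture(scope="session")
def sphere():
    return SphereSDF(center=(0.0, 0.0, 0.0), radius=5.0)


@pytest.fixture(scope="session")
def sphere_system():
    """4 identical analytic spheres, k=128, fully optimized (shared)."""
    surfaces = [SphereSDF(radius=5.0) for _ in range(4)]
    return optimize(surfaces, OptimizerConfig(k_target=128, seed=0))


@pytest.fixture(scope="session")
def small_population():
    """Tiny two-group null population + SDFs (shared across tests)."""
    spec = PopulationSpec(
        groups=[GroupSpec("a", 4, 0.0), GroupSpec("b", 4, 0.0)],
        grid_shape=36,
        voxel_spacing=0.65,
        seed=11,
    )
    volumes, truths = generate_population(spec)
    surfaces = [mask_to_sdf(v, smoothing_sigma=0.65) for v in volumes]
    return spec, volumes, truths, surfaces


FAST_OPTIMIZER = dict(iters_spread=15, iters_joint=6, iters_joint_final=10)


@pytest.fixture(scope="session")
def small_system(small_population):
    _, _, _, surfaces = small_population
    return optimize(surfaces, OptimizerConfig(k_target=32, seed=3, **FAST_OPTIMIZER))
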