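"""Particle optimizer: entropies, gradients, schedule, invariants."""

import numpy as np
import pytest

from shapecorr.correspond import (
    OptimizerConfig,
    adapt_sigmas,
    ensemble_entropy,
    ensemble_entropy_gradient,
    initialize_particles,
    load_particles,
    optimize,
    sampling_entropy,
    sampling_entropy_gradient,
    save_particles,
    split_particles,
)
from shapecorr.synth import EffectSpec, RadialShape
from shapecorr.volumes import PlaneSDF, SphereSDF, mask_to_sdf


def nn_distances(x):
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


# ------------------------------------------------------------------ config


def test_config_validation():
    with pytest.raises(ValueError, match="power of two"):
        OptimizerConfig(k_target=100)
    with pytest.raises(ValueError, match="power of two"):
        OptimizerConfig(k_target=0)
    OptimizerConfig(k_target=1)  # degenerate but legal


# ----------------------------------------------------------- initialization


def test_initialize_on_sphere(sphere):
    ps = initialize_particles([sphere, sphere], seed=0)
    assert ps.positions.shape == (2, 1, 3)
    r = np.linalg.norm(ps.positions[0, 0])
    assert abs(r - 5.0) <= ps.tols[0]


def test_initialize_identical_surfaces_identical_particles(sphere):
    ps = initialize_particles([sphere, sphere, sphere], seed=0)
    for a in range(1, 3):
        np.testing.assert_array_equal(ps.positions[a], ps.positions[0])


def test_initialize_single_surface_rejected(sphere):
    with pytest.raises(ValueError, match="at least 2"):
        initialize_particles([sphere], seed=0)


# ------------------------------------------------------------------- split


def test_split_doubles_count(sphere):
    ps = initialize_particles([sphere, sphere], seed=0)
    ps2 = split_particles(ps, rng=np.random.default_rng(1))
    assert ps2.k == 2
    ps4 = split_particles(ps2, rng=np.random.default_rng(2))
    assert ps4.k == 4
    for sys in (ps2, ps4):
        for a in range(sys.n_shapes):
            assert np.abs(sys.surfaces[a].value(sys.positions[a])).max() <= sys.tols[a]


def test_split_deterministic(sphere):
    ps = initialize_particles([sphere, sphere], seed=0)
    a = split_particles(ps, rng=np.random.default_rng(7))
    b = split_particles(ps, rng=np.random.default_rng(7))
    np.testing.assert_array_equal(a.positions, b.positions)


def test_split_child_distance_on_plane():
    # flat region oracle: after projection onto a plane, the child lands at
    # the in-plane component of the offset, so parent-child distance is at
    # most the offset length <= a few perturbation sd; check <= 2 * pert
    # holds for the median (Gaussian tails can exceed any fixed multiple)
    plane = PlaneSDF(normal=(0, 0, 1), extent=10.0)
    ps = initialize_particles([plane, plane], seed=0)
    k = 64
    pert = 0.5
    sysk = ps
    rng = np.random.default_rng(0)
    while sysk.k < k:
        sysk = split_particles(sysk, perturbation=pert, rng=rng)
    parents = sysk.positions[0][: sysk.k // 2]
    children = sysk.positions[0][sysk.k // 2 :]
    d = np.linalg.norm(children - parents, axis=1)
    assert np.median(d) <= 2 * pert
    assert d.max() <= 5 * pert


def test_split_invalid_perturbation(sphere):
    ps = initialize_particles([sphere, sphere], seed=0)
    with pytest.raises(ValueError):
        split_particles(ps, perturbation=0.0)


# ------------------------------------------------- sampling entropy gradient


def test_two_particles_on_plane_equal_opposite():
    x = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    sig = np.array([1.0, 1.0])
    g = sampling_entropy_gradient(x, sig)
    np.testing.assert_allclose(g[0], -g[1], atol=1e-12)
    # repulsion acts along the separating direction
    assert abs(g[0][1]) < 1e-12 and abs(g[0][2]) < 1e-12


def test_hexagonal_ring_center_balanced():
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    ring = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
    x = np.vstack([[0.0, 0.0, 0.0], ring])
    sig = np.ones(7)
    g = sampling_entropy_gradient(x, sig)
    assert np.linalg.norm(g[0]) < 1e-12


def test_sampling_gradient_matches_finite_differences():
    rng = np.random.default_rng(42)
    for _ in range(5):
        k = rng.integers(4, 9)
        x = np.zeros((k, 3))
        x[:, :2] = rng.normal(size=(k, 2))  # planar configuration
        sig = rng.uniform(0.5, 1.5, size=k)
        g = sampling_entropy_gradient(x, sig)
        eps = 1e-6
        num = np.zeros_like(x)
        for i in range(k):
            for c in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, c] += eps
                xm[i, c] -= eps
                num[i, c] = -(
                    sampling_entropy(xp, sig) - sampling_entropy(xm, sig)
                ) / (2 * eps)
        scale = np.abs(num).max()
        assert np.abs(g - num).max() / scale < 1e-4


def test_coincident_particles_no_nan():
    x = np.zeros((3, 3))
    sig = np.ones(3)
    g = sampling_entropy_gradient(x, sig, grad_cap=10.0)
    assert np.all(np.isfinite(g))
    assert np.linalg.norm(g, axis=1).max() <= 10.0 + 1e-9


def test_sampling_entropy_needs_two():
    with pytest.raises(ValueError):
        sampling_entropy(np.zeros((1, 3)), np.ones(1))


# ------------------------------------------------- ensemble entropy gradient


def test_ensemble_identical_configs_zero_gradient():
    y = np.tile(np.arange(12.0), (4, 1))
    g = ensemble_entropy_gradient(y, alpha=0.1)
    assert np.abs(g).max() < 1e-12


def test_ensemble_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    y = rng.normal(size=(3, 12))  # n=3 shapes, k=4 particles
    alpha = 0.2
    g = ensemble_entropy_gradient(y, alpha)
    eps = 1e-6
    num = np.zeros_like(y)
    for i in range(3):
        for j in range(12):
            yp, ym = y.copy(), y.copy()
            yp[i, j] += eps
            ym[i, j] -= eps
            num[i, j] = (
                ensemble_entropy(yp, alpha) - ensemble_entropy(ym, alpha)
            ) / (2 * eps)
    assert np.abs(g - num).max() / np.abs(num).max() < 1e-4


def test_ensemble_alpha_monotonicity():
    # lambda / (lambda + alpha) decreases in alpha, so the gradient of the
    # log-det term can only shrink when alpha doubles
    rng = np.random.default_rng(9)
    y = rng.normal(size=(5, 30))
    alphas = [0.01, 0.02, 0.04, 0.08, 0.16]
    norms = [np.linalg.norm(ensemble_entropy_gradient(y, a)) for a in alphas]
    assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))


# ---------------------------------------------------------------- optimize


def test_sphere_population_uniform_sampling(sphere_system):
    nn = nn_distances(sphere_system.positions[0])
    assert nn.std() / nn.mean() < 0.15


def test_identical_shapes_collapse_ensemble(sphere_system):
    y = sphere_system.flatten()
    p = y - y.mean(axis=0, keepdims=True)
    lam = np.linalg.eigvalsh(p @ p.T / (sphere_system.n_shapes - 1))
    assert lam.max() < 1e-6


def test_particles_on_surface(sphere_system):
    assert sphere_system.max_residual() <= sphere_system.tols.max() * 1.5


def test_optimize_deterministic(small_population):
    from conftest import FAST_OPTIMIZER

    _, _, _, surfaces = small_population
    cfg = OptimizerConfig(k_target=16, seed=5, **FAST_OPTIMIZER)
    a = optimize(surfaces, cfg)
    b = optimize(surfaces, cfg)
    np.testing.assert_array_equal(a.positions, b.positions)


def test_cost_monotone_over_accepted_steps(small_system):
    assert len(small_system.q_history) > 0
    for q0, q1 in small_system.q_history:
        assert q1 <= q0 + 1e-9 * (1.0 + abs(q0))


def test_scaling_equivariance():
    cfg = OptimizerConfig(k_target=32, seed=0)
    pos1 = optimize([SphereSDF(radius=4.0)] * 3, cfg).positions
    pos2 = optimize([SphereSDF(radius=8.0)] * 3, cfg).positions
    assert np.abs(pos2 - 2.0 * pos1).max() / np.abs(pos1).max() < 1e-3


def test_one_parameter_family_first_mode_dominates():
    from shapecorr.shapespace import center_and_scale, fit_pca, procrustes_rotate

    params = np.linspace(6.0, 9.0, 8)
    surfs = [
        mask_to_sdf(
            RadialShape(axes=(a, 5.0, 3.0), exponent=2.0).voxelize(0.5, (48,) * 3),
            smoothing_sigma=0.5,
        )
        for a in params
    ]
    ps = optimize(surfs, OptimizerConfig(k_target=128, seed=0))
    sm = procrustes_rotate(center_and_scale(ps.positions))
    model = fit_pca(sm)
    assert model.variance_share()[0] > 0.95
    assert abs(np.corrcoef(model.loadings[:, 0], params)[0, 1]) > 0.9


def test_correspondence_recovers_planted_deformation():
    # population generated by a known smooth radial deformation of a common
    # base; undoing the deformation analytically must remove most of the
    # across-shape variance of the particles
    amps = [0.0, 0.3, 0.6, 0.9, 1.2]
    shapes = [
        RadialShape(
            axes=(6.0, 5.0, 4.0),
            exponent=2.0,
            effect=EffectSpec("lateral_bump", amplitude=a, extent=1.4),
        )
        for a in amps
    ]
    surfs = [mask_to_sdf(s.voxelize(0.5, (48,) * 3), 0.5) for s in shapes]
    ps = optimize(surfs, OptimizerConfig(k_target=64, seed=1))
    pos = ps.positions
    var_before = pos.var(axis=0).sum()
    corrected = np.empty_like(pos)
    for i, shape in enumerate(shapes):
        p = pos[i]
        r = np.linalg.norm(p, axis=1)
        u = p / r[:, None]
        r0 = r - shape.displacement(u)  # undo the planted radial effect
        corrected[i] = u * r0[:, None]
    var_after = corrected.var(axis=0).sum()
    assert var_after < 0.10 * var_before


def test_nonconvergence_flagged_not_raised(small_population):
    _, _, _, surfaces = small_population
    # absurdly tight tolerance budget: must return best-so-far with warnings
    cfg = OptimizerConfig(
        k_target=8, seed=0, iters_spread=1, iters_joint=1, iters_joint_final=1,
        surface_tol_rel=1e-9, max_backtracks=1,
    )
    ps = optimize(surfaces, cfg)
    assert ps.positions.shape[1] == 8
    if not ps.converged:
        assert ps.warnings


# ------------------------------------------------------------- persistence


def test_save_load_round_trip(tmp_path, small_system):
    manifest = save_particles(small_system, tmp_path)
    pos, ids = load_particles(manifest)
    np.testing.assert_allclose(pos, small_system.positions, atol=1e-9)
    assert len(ids) == small_system.n_shapes


def test_adapt_sigmas_neighbor_count():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(50, 3))
    target = 6.0
    sig = adapt_sigmas(x, target)
    d2 = ((x[:, None] - x[None, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    counts = np.exp(-d2 / (2 * sig[:, None] ** 2)).sum(axis=1)
    np.testing.assert_allclose(counts, target, rtol=1e-3)
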