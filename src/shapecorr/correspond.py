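"""Particle-based correspondence optimization on implicit surfaces.

``k`` particles are placed on each of ``n`` surfaces.  Per shape, particles
spread out by ascending a Parzen-window entropy of their own configuration;
across shapes, the ensemble of flattened configurations is pulled toward a
low-entropy (compact-covariance) model.  The combined objective that is
minimized over particle positions is::

    Q = w_e * H(Z) - w_s * sum_a H(P_a)

where ``H(P_a)`` is the per-shape sampling entropy (isotropic Gaussian
kernels, adaptive per-particle widths) and ``H(Z) = 1/2 sum_j log(l_j + a)``
with ``l_j`` the eigenvalues of the ensemble covariance and ``a > 0`` a
regularizer.  Particle index ``i`` on shape 1 corresponds to index ``i`` on
every other shape; the split schedule preserves this by construction, and
the ensemble term enforces it at optimality.

All gradients are projected into the local surface tangent plane and every
accepted step is followed by Newton re-projection onto the zero level set,
so the surface constraint is kept exact rather than penalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from . import io as scio
from .volumes import ImplicitSurface, ProjectionError, project_to_surface

__all__ = [
    "OptimizerConfig",
    "ParticleSystem",
    "InitializationError",
    "SplitError",
    "initialize_particles",
    "split_particles",
    "adapt_sigmas",
    "sampling_entropy",
    "sampling_entropy_gradient",
    "ensemble_entropy",
    "ensemble_entropy_gradient",
    "optimize",
    "save_particles",
    "load_particles",
]


class InitializationError(RuntimeError):
    pass


class SplitError(RuntimeError):
    pass


@dataclass
class OptimizerConfig:
    """Hyperparameters of the particle optimizer.

    ``k_target`` must be a power of two times the initial particle count
    (one), since particles double at each split.  Defaults were chosen for
    robust behavior on smooth closed surfaces at ``k <= 1024``, not tuned
    to any particular dataset.
    """

    k_target: int = 128
    weight_sampling: float = 1.0
    weight_ensemble: float = 1.0
    alpha_rel: float = 0.05        # ensemble regularizer, x mean eigenvalue
    alpha_floor_rel: float = 1e-8  # absolute floor, x (shape scale)^2
    split_perturbation_frac: float = 0.3   # x mean nearest-neighbor distance
    neighbor_target: float = 3.0   # weighted neighbor count fixing sigma
    iters_spread: int = 40         # per level, reference-shape spread-only
    iters_joint: int = 30          # per level, combined descent
    iters_joint_final: int = 80    # extra combined descent at k_target
    step_frac: float = 0.25        # initial step as fraction of sigma
    conv_tol_frac: float = 0.005   # mean displacement < frac * mean sigma
    max_backtracks: int = 12
    surface_tol_rel: float = 1e-3  # projection tol, x shape scale
    grad_cap: float = 1e6
    seed: int = 0

    def __post_init__(self):
        k = self.k_target
        if k < 1 or (k & (k - 1)) != 0:
            raise ValueError("k_target must be a positive power of two")
        if self.alpha_rel <= 0 and self.alpha_floor_rel <= 0:
            raise ValueError("ensemble regularization must be positive")
        for name in ("step_frac", "conv_tol_frac", "split_perturbation_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ParticleSystem:
    """``n`` shapes x ``k`` corresponding particles in world coordinates."""

    positions: np.ndarray              # (n, k, 3)
    surfaces: list[ImplicitSurface]
    sigmas: np.ndarray                 # (n, k) kernel widths
    tols: np.ndarray                   # (n,) per-shape surface tolerance
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    q_history: list[tuple[float, float]] = field(default_factory=list)
    iterations: dict = field(default_factory=dict)

    @property
    def n_shapes(self) -> int:
        return self.positions.shape[0]

    @property
    def k(self) -> int:
        return self.positions.shape[1]

    def flatten(self) -> np.ndarray:
        """(n, 3k) matrix of flattened configurations (x1 y1 z1 x2 ...)."""
        return self.positions.reshape(self.n_shapes, -1)

    def max_residual(self) -> float:
        return max(
            float(np.abs(s.value(x)).max())
            for s, x in zip(self.surfaces, self.positions)
        )


# ------------------------------------------------------------- entropies


def _pairwise_sq(x: np.ndarray) -> np.ndarray:
    d = x[:, None, :] - x[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def adapt_sigmas(x: np.ndarray, target: float = 6.0) -> np.ndarray:
    """Per-particle Gaussian widths such that each particle's weighted
    neighbor count ``sum_j exp(-d_ij^2 / 2 s_i^2)`` hits ``target``
    (clipped to what ``k - 1`` neighbors can supply).  Bisection in log s.
    """
    k = x.shape[0]
    if k < 2:
        return np.ones(k)
    d2 = _pairwise_sq(x)
    np.fill_diagonal(d2, np.inf)
    t = min(target, 0.75 * (k - 1))
    dmin = np.sqrt(np.min(d2, axis=1))
    dmin = np.maximum(dmin, 1e-12 * max(dmin.max(), 1.0))
    lo = np.log(dmin) - 7.0
    hi = np.log(np.sqrt(np.max(d2[np.isfinite(d2)])) + dmin) + 7.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        s2 = np.exp(2.0 * mid)
        cnt = np.exp(-d2 / (2.0 * s2[:, None])).sum(axis=1)
        high = cnt > t
        hi[high] = mid[high]
        lo[~high] = mid[~high]
    return np.exp(0.5 * (lo + hi))


def sampling_entropy(x: np.ndarray, sigmas: np.ndarray) -> float:
    """Parzen estimate of the configuration entropy of one shape's particles.

    ``H = -(1/k) sum_i log p_i`` with
    ``p_i = (1/(k-1)) sum_{j != i} N(x_i; x_j, s_j^2 I)`` (3D isotropic
    Gaussian kernels carried by the source particle ``j``).
    """
    k = x.shape[0]
    if k < 2:
        raise ValueError("sampling entropy needs k >= 2")
    d2 = _pairwise_sq(x)
    s2 = np.asarray(sigmas, dtype=float) ** 2
    logw = -d2 / (2.0 * s2[None, :]) - 1.5 * np.log(2.0 * np.pi * s2[None, :])
    np.fill_diagonal(logw, -np.inf)
    logp = logsumexp(logw, axis=1) - np.log(k - 1)
    return float(-np.mean(logp))


def sampling_entropy_gradient(
    x: np.ndarray,
    sigmas: np.ndarray,
    surface: ImplicitSurface | None = None,
    grad_cap: float = 1e6,
) -> np.ndarray:
    """Exact gradient of ``-H`` (the term entering Q) w.r.t. positions.

    Descending this gradient spreads particles apart.  Kernel widths are
    treated as constants.  When ``surface`` is given the result is
    projected into each particle's tangent plane.  Coincident particles
    yield finite (capped) values, never NaN.
    """
    k = x.shape[0]
    if k < 2:
        raise ValueError("gradient needs k >= 2")
    diff = x[:, None, :] - x[None, :, :]          # diff[i, j] = x_i - x_j
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    s2 = np.asarray(sigmas, dtype=float) ** 2
    logw = -d2 / (2.0 * s2[None, :]) - 1.5 * np.log(2.0 * np.pi * s2[None, :])
    np.fill_diagonal(logw, -np.inf)
    lse = logsumexp(logw, axis=1, keepdims=True)
    a = np.exp(logw - lse)                        # a[i, j] = W_ij / sum_j' W_ij'
    # d(sum_i log p_i)/dx_l, two terms: l as the query point and as a kernel center
    term1 = -np.einsum("lj,ljc->lc", a / s2[None, :], diff)
    term2 = np.einsum("il,ilc->lc", a, diff) / s2[:, None]
    g = (term1 + term2) / k
    g = np.nan_to_num(g, nan=0.0, posinf=grad_cap, neginf=-grad_cap)
    norms = np.linalg.norm(g, axis=1)
    over = norms > grad_cap
    if over.any():
        g[over] *= (grad_cap / norms[over])[:, None]
    if surface is not None:
        g = _tangent_project(g, surface, x)
    return g


def _tangent_project(
    g: np.ndarray, surface: ImplicitSurface, x: np.ndarray
) -> np.ndarray:
    nrm = surface.gradient(x)
    mag = np.linalg.norm(nrm, axis=-1, keepdims=True)
    nrm = np.where(mag > 1e-12, nrm / np.maximum(mag, 1e-12), 0.0)
    return g - np.einsum("ic,ic->i", g, nrm)[:, None] * nrm


def ensemble_entropy(y: np.ndarray, alpha: float) -> float:
    """``H(Z) = 1/2 sum_j log(l_j + alpha)`` over the dual (n x n)
    covariance eigenvalues of the centered flattened configurations."""
    n = y.shape[0]
    p = y - y.mean(axis=0, keepdims=True)
    c = p @ p.T / (n - 1)
    lam = np.linalg.eigvalsh(c)
    return float(0.5 * np.sum(np.log(np.maximum(lam, 0.0) + alpha)))


def ensemble_entropy_gradient(
    y: np.ndarray,
    alpha: float,
    surfaces: list[ImplicitSurface] | None = None,
) -> np.ndarray:
    """Gradient of the ensemble entropy w.r.t. the (n, 3k) configuration
    matrix, computed in the dual space.  Returns (n, k, 3) when surfaces
    are supplied (tangent-projected), else (n, 3k).
    """
    n, d3k = y.shape
    alpha = max(alpha, 1e-30)
    p = y - y.mean(axis=0, keepdims=True)
    c = p @ p.T / (n - 1)
    inv = np.linalg.inv(c + alpha * np.eye(n))
    g = inv @ p / (n - 1)
    g = g - g.mean(axis=0, keepdims=True)  # chain rule through row centering
    if surfaces is None:
        return g
    k = d3k // 3
    g3 = g.reshape(n, k, 3).copy()
    x3 = y.reshape(n, k, 3)
    for a in range(n):
        g3[a] = _tangent_project(g3[a], surfaces[a], x3[a])
    return g3


# ---------------------------------------------------------- construction


def _surface_tol(surface: ImplicitSurface, rel: float) -> float:
    return max(rel * surface.scale_hint(), 1e-12)


def initialize_particles(
    surfaces: list[ImplicitSurface],
    seed: int = 0,
    surface_tol_rel: float = 1e-3,
) -> ParticleSystem:
    """One particle per shape, at the surface point nearest the foreground
    centroid.  Deterministic given the inputs."""
    if len(surfaces) < 2:
        raise ValueError("ensemble needs at least 2 surfaces")
    tols = np.array([_surface_tol(s, surface_tol_rel) for s in surfaces])
    pos = np.zeros((len(surfaces), 1, 3))
    for a, s in enumerate(surfaces):
        try:
            pos[a, 0] = project_to_surface(
                s.centroid_hint(), s, tols[a], max_iter=100,
                rng=np.random.default_rng([seed, 0xA5EED]),
            )
        except ProjectionError as exc:
            raise InitializationError(
                f"initialization failed on shape {a}: {exc}"
            ) from exc
    sig = np.array([[0.5 * s.scale_hint()] for s in surfaces])
    return ParticleSystem(positions=pos, surfaces=surfaces, sigmas=sig, tols=tols)


def split_particles(
    ps: ParticleSystem,
    perturbation: float | None = None,
    rng: np.random.Generator | None = None,
) -> ParticleSystem:
    """Double the particle count.  Each particle spawns one child displaced
    by the same random offset for a given particle index on every shape
    (correspondence is preserved by construction), then re-projected.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n, k, _ = ps.positions.shape
    if perturbation is None:
        if k >= 2:
            nnd = []
            for a in range(n):
                d2 = _pairwise_sq(ps.positions[a])
                np.fill_diagonal(d2, np.inf)
                nnd.append(np.sqrt(d2.min(axis=1)).mean())
            perturbation = 0.3 * float(np.mean(nnd))
        else:
            perturbation = 0.5 * float(
                np.mean([s.scale_hint() for s in ps.surfaces])
            )
    if perturbation <= 0:
        raise ValueError("perturbation must be > 0")
    offsets = rng.normal(scale=perturbation, size=(k, 3))
    children = np.zeros_like(ps.positions)
    for a, s in enumerate(ps.surfaces):
        try:
            children[a] = project_to_surface(
                ps.positions[a] + offsets, s, ps.tols[a], max_iter=100, rng=rng
            )
        except ProjectionError as exc:
            raise SplitError(f"split projection failed on shape {a}: {exc}") from exc
    new_pos = np.concatenate([ps.positions, children], axis=1)
    new_sig = np.concatenate([ps.sigmas, ps.sigmas], axis=1)
    return ParticleSystem(
        positions=new_pos,
        surfaces=ps.surfaces,
        sigmas=new_sig,
        tols=ps.tols,
        converged=ps.converged,
        warnings=list(ps.warnings),
        q_history=list(ps.q_history),
        iterations=dict(ps.iterations),
    )


# ----------------------------------------------------------- optimization


def _safe_project(x, surface, tol, fallback):
    """Project; particles that fail revert to their fallback position."""
    try:
        return project_to_surface(x, surface, tol, max_iter=30)
    except ProjectionError:
        out = x.copy()
        for i in range(len(x)):
            try:
                out[i] = project_to_surface(x[i], surface, tol, max_iter=60)
            except ProjectionError:
                out[i] = fallback[i]
        return out


def _propagate_reference(ps: ParticleSystem, ref: int = 0) -> None:
    """Copy the reference shape's configuration to every other shape by
    projection.  For populations of similar, similarly-posed shapes this
    yields near-exact initial correspondence; the joint phase then refines
    per-shape positions.  Independent per-shape relaxation is avoided
    because on near-symmetric shapes it drops different specimens into
    different symmetry basins that the ensemble term cannot merge."""
    for a in range(ps.n_shapes):
        if a == ref:
            continue
        ps.positions[a] = _safe_project(
            ps.positions[ref].copy(), ps.surfaces[a], ps.tols[a], ps.positions[a]
        )
        ps.sigmas[a] = ps.sigmas[ref]


def _spread_phase(
    ps: ParticleSystem, cfg: OptimizerConfig, shapes: list[int] | None = None
) -> None:
    """Per-shape uniform-spread relaxation (sampling entropy only)."""
    total_iters = 0
    for a in shapes if shapes is not None else range(ps.n_shapes):
        s = ps.surfaces[a]
        x = ps.positions[a]
        if x.shape[0] < 2:
            continue
        sig = adapt_sigmas(x, cfg.neighbor_target)
        fx = -sampling_entropy(x, sig)
        gamma = None
        for it in range(cfg.iters_spread):
            if it > 0 and it % 5 == 0:
                sig = adapt_sigmas(x, cfg.neighbor_target)
                fx = -sampling_entropy(x, sig)
            g = sampling_entropy_gradient(x, sig, s, cfg.grad_cap)
            gnorm = np.linalg.norm(g, axis=1)
            med = np.median(gnorm[gnorm > 0]) if (gnorm > 0).any() else 0.0
            if med == 0.0:
                break
            if gamma is None:
                gamma = cfg.step_frac * float(np.median(sig)) / med
            accepted = False
            for _ in range(cfg.max_backtracks):
                step = -gamma * g
                cap = 0.5 * sig[:, None]
                nrm = np.linalg.norm(step, axis=1, keepdims=True)
                step = np.where(nrm > cap, step * cap / np.maximum(nrm, 1e-30), step)
                xn = _safe_project(x + step, s, ps.tols[a], x)
                fn = -sampling_entropy(xn, sig)
                if fn <= fx + 1e-12 * (1.0 + abs(fx)):
                    accepted = True
                    break
                gamma *= 0.5
            if not accepted:
                break
            disp = float(np.linalg.norm(xn - x, axis=1).mean())
            x, fx = xn, fn
            gamma *= 1.1
            total_iters += 1
            if disp < cfg.conv_tol_frac * float(np.mean(sig)):
                break
        ps.positions[a] = x
        ps.sigmas[a] = sig if x.shape[0] >= 2 else ps.sigmas[a]
    ps.iterations["spread"] = ps.iterations.get("spread", 0) + total_iters


def _joint_objective(ps, sigs, alpha, cfg):
    q = cfg.weight_ensemble * ensemble_entropy(ps.flatten(), alpha)
    for a in range(ps.n_shapes):
        q -= cfg.weight_sampling * sampling_entropy(ps.positions[a], sigs[a])
    return q


def _joint_phase(ps: ParticleSystem, cfg: OptimizerConfig, iters: int | None = None) -> None:
    """Combined sampling + ensemble descent with global backtracking."""
    n, k, _ = ps.positions.shape
    iters = iters if iters is not None else cfg.iters_joint
    scale2 = float(np.mean([s.scale_hint() for s in ps.surfaces]) ** 2)
    sigs = np.stack(
        [adapt_sigmas(ps.positions[a], cfg.neighbor_target) for a in range(n)]
    )
    gamma = None
    stalled = 0
    for it in range(iters):
        if it > 0 and it % 5 == 0:
            sigs = np.stack(
                [adapt_sigmas(ps.positions[a], cfg.neighbor_target) for a in range(n)]
            )
            gamma = None  # step scale is relative to sigma; re-estimate
        y = ps.flatten()
        p = y - y.mean(axis=0, keepdims=True)
        lam = np.linalg.eigvalsh(p @ p.T / max(n - 1, 1))
        alpha = cfg.alpha_rel * float(np.maximum(lam, 0.0).mean()) \
            + cfg.alpha_floor_rel * scale2
        q0 = _joint_objective(ps, sigs, alpha, cfg)
        g_ens = ensemble_entropy_gradient(y, alpha, ps.surfaces)
        g = cfg.weight_ensemble * g_ens
        for a in range(n):
            g[a] += cfg.weight_sampling * sampling_entropy_gradient(
                ps.positions[a], sigs[a], ps.surfaces[a], cfg.grad_cap
            )
        gnorm = np.linalg.norm(g, axis=2)
        gmax = float(gnorm.max())
        if gmax == 0.0:
            break
        if gamma is None:
            # scale to the LARGEST gradient: the ensemble term is far more
            # curved than the sampling term and overshoots otherwise
            gamma = cfg.step_frac * float(np.median(sigs)) / gmax
        old = ps.positions.copy()
        accepted = False
        for _ in range(cfg.max_backtracks):
            step = -gamma * g
            cap = 0.5 * sigs[..., None]
            nrm = np.linalg.norm(step, axis=2, keepdims=True)
            step = np.where(nrm > cap, step * cap / np.maximum(nrm, 1e-30), step)
            cand = old + step
            for a in range(n):
                cand[a] = _safe_project(cand[a], ps.surfaces[a], ps.tols[a], old[a])
            ps.positions = cand
            q1 = _joint_objective(ps, sigs, alpha, cfg)
            if q1 <= q0 + 1e-12 * (1.0 + abs(q0)):
                accepted = True
                break
            gamma *= 0.5
            ps.positions = old
        if not accepted:
            stalled += 1
            if stalled >= 3:
                break
            gamma = None  # re-estimate from the next gradient
            continue
        stalled = 0
        ps.q_history.append((float(q0), float(q1)))
        gamma *= 1.1
        disp = float(np.linalg.norm(ps.positions - old, axis=2).mean())
        ps.iterations["joint"] = ps.iterations.get("joint", 0) + 1
        if disp < cfg.conv_tol_frac * float(np.mean(sigs)):
            break
    ps.sigmas = sigs


def optimize(
    surfaces: list[ImplicitSurface], cfg: OptimizerConfig | None = None
) -> ParticleSystem:
    """Run the full schedule: init (k=1), split-and-spread up to
    ``k_target``, then the joint sampling+ensemble phase.

    Non-convergence is reported via ``result.converged`` / ``.warnings``
    (best-so-far positions are returned), not raised, so pipelines can
    inspect.  Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg if cfg is not None else OptimizerConfig()
    rng = np.random.default_rng([cfg.seed, 0x5F117])  # distinct from init stream
    ps = initialize_particles(surfaces, seed=cfg.seed, surface_tol_rel=cfg.surface_tol_rel)
    use_ensemble = cfg.weight_ensemble > 0 and len(surfaces) >= 2
    while ps.k < cfg.k_target:
        ps = split_particles(ps, rng=rng)
        _spread_phase(ps, cfg, shapes=[0])
        _propagate_reference(ps, ref=0)
        # keep correspondence tight at every scale, not only at the end
        if use_ensemble and ps.k < cfg.k_target:
            _joint_phase(ps, cfg, iters=cfg.iters_joint)
    if use_ensemble:
        _joint_phase(ps, cfg, iters=cfg.iters_joint_final)
    else:
        _spread_phase(ps, cfg)
    resid = ps.max_residual()
    tol_max = float(ps.tols.max())
    if resid > tol_max * 1.5:
        ps.converged = False
        ps.warnings.append(
            f"max surface residual {resid:.3g} exceeds tolerance {tol_max:.3g}"
        )
    return ps


# ----------------------------------------------------------- persistence


def save_particles(ps: ParticleSystem, outdir: str | Path, ids=None) -> Path:
    """One ``x y z`` point file per shape plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = ids if ids is not None else [f"shape_{a:03d}" for a in range(ps.n_shapes)]
    files = []
    for a, sid in enumerate(ids):
        f = f"{sid}.particles"
        scio.write_points(outdir / f, ps.positions[a])
        files.append(f)
    manifest = {
        "n_shapes": ps.n_shapes,
        "k": ps.k,
        "converged": ps.converged,
        "warnings": ps.warnings,
        "files": files,
        "ids": list(ids),
    }
    mpath = outdir / "particles.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_particles(manifest_path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load positions (n, k, 3) and shape ids from a saved manifest."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    pos = np.stack(
        [scio.read_points(mpath.parent / f) for f in manifest["files"]]
    )
    return pos, manifest["ids"]
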