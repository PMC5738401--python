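"""Two-group inference in PCA space.

Hotelling T² on retained PCA loadings (parametric F transform and
permutation null), the multivariate Levene variance battery (mean/median
centers, parametric and permutation p), and the Fisher-discriminant
back-projection that turns the test's direction into per-correspondence
difference vectors for visualization.

The T² prefactor: the standard two-sample form
``n_a n_b (n_a + n_b - 2) / (n_a + n_b)`` is used by default so the
parametric F calibration is exact; an ``as_printed`` variant
(``n_a + n_b - 2``) is provided for comparison.  The permutation p-value
is invariant to this choice since the prefactor is constant across
permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

from .shapespace import PCAModel, ShapeMatrix

__all__ = [
    "GroupComparison",
    "LeveneResult",
    "PermutationResult",
    "hotelling_t2",
    "parametric_p",
    "permutation_p",
    "map_discriminant",
    "levene_tests",
    "group_mean_shape",
    "compare_groups",
]


@dataclass
class PermutationResult:
    p: float
    n_perms: int
    exhaustive: bool
    n_redrawn: int = 0


@dataclass
class LeveneResult:
    """p-values of the four variance-test variants."""

    mean_p: float
    median_p: float
    randomized_mean_p: float
    randomized_median_p: float
    n_perms: int


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    m: int
    t2: float
    parametric_p: float
    permutation_p: float
    n_perms: int
    permutation_exhaustive: bool
    w: np.ndarray                    # (m,) discriminant in loading space
    w_hat: np.ndarray                # (3k,) discriminant in shape space
    arrows: np.ndarray               # (k, 3)
    levene: LeveneResult | None = None


def _scatter(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    d = x - mu
    return mu, d.T @ d


def hotelling_t2(
    a: np.ndarray, b: np.ndarray, prefactor: str = "standard"
) -> tuple[float, np.ndarray]:
    """Two-sample Hotelling T² and the Fisher discriminant ``w``.

    ``w = (S_a + S_b)^-1 (mu_a - mu_b)`` with S the within-group scatter
    matrices (sums of outer products of deviations), and
    ``T² = pref * (mu_a - mu_b)' w``.

    Raises
    ------
    ValueError
        On a prefactor name that is not ``standard``/``as_printed``, on
        too-few samples, or on a singular pooled scatter.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, m = a.shape
    nb = b.shape[0]
    if na + nb - 2 <= m:
        raise ValueError(
            f"need n_a + n_b - 2 > m for an invertible pooled scatter "
            f"(got n_a={na}, n_b={nb}, m={m}); reduce the mode count"
        )
    mu_a, s_a = _scatter(a)
    mu_b, s_b = _scatter(b)
    delta = mu_a - mu_b
    pooled = s_a + s_b
    try:
        w = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled scatter; reduce the number of modes m"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise ValueError("singular pooled scatter; reduce the number of modes m")
    if prefactor == "standard":
        pref = na * nb * (na + nb - 2) / (na + nb)
    elif prefactor == "as_printed":
        pref = na + nb - 2
    else:
        raise ValueError(f"unknown prefactor {prefactor!r}")
    t2 = float(pref * delta @ w)
    return max(t2, 0.0), w


def parametric_p(t2: float, n_a: int, n_b: int, m: int) -> float:
    """p-value from the F transform of T²:
    ``F = T² (N - m - 1) / (m (N - 2))`` on (m, N - m - 1) dof."""
    ndf = n_a + n_b - m - 1
    if ndf < 1 or m < 1:
        raise ValueError("degrees of freedom must be positive")
    f = t2 * ndf / (m * (n_a + n_b - 2))
    return float(sps.f.sf(f, m, ndf))


def _t2_for_labels(
    x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, prefactor: str
) -> float:
    try:
        t2, _ = hotelling_t2(x[idx_a], x[idx_b], prefactor=prefactor)
        return t2
    except ValueError:
        return np.nan


def permutation_p(
    a: np.ndarray,
    b: np.ndarray,
    n_perms: int = 20000,
    seed: int = 0,
    prefactor: str = "standard",
) -> PermutationResult:
    """Permutation p-value for the two-sample T².

    Group labels are permuted uniformly at random ``n_perms`` times and
    ``p = (1 + #{T²_perm >= T²_obs}) / (1 + n_perms)``.  When the total
    number of assignments C(n_a + n_b, n_a) is at most ``n_perms``, the
    exact enumeration fraction over all assignments is returned instead.
    Permutations yielding a singular scatter are re-drawn (count logged).
    The result is invariant to the T² ``prefactor`` (a constant multiplier
    cancels in the rank comparison); the parameter exists to make that
    property testable.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    x = np.vstack([a, b])
    all_idx = np.arange(na + nb)
    t_obs, _ = hotelling_t2(a, b, prefactor=prefactor)
    total = comb(na + nb, na)
    if total <= n_perms:
        count = 0
        valid = 0
        for combo in itertools.combinations(range(na + nb), na):
            ia = np.array(combo)
            ib = np.setdiff1d(all_idx, ia, assume_unique=True)
            t = _t2_for_labels(x, ia, ib, prefactor)
            if np.isnan(t):
                t = np.inf  # conservative for degenerate splits
            valid += 1
            if t >= t_obs - 1e-12 * max(1.0, abs(t_obs)):
                count += 1
        return PermutationResult(
            p=count / valid, n_perms=valid, exhaustive=True
        )
    rng = np.random.default_rng(seed)
    count = 0
    redrawn = 0
    done = 0
    while done < n_perms:
        perm = rng.permutation(na + nb)
        t = _t2_for_labels(x, perm[:na], perm[na:], prefactor)
        if np.isnan(t):
            redrawn += 1
            if redrawn > 10 * n_perms:
                raise RuntimeError("too many degenerate permutations")
            continue
        if t >= t_obs - 1e-12 * max(1.0, abs(t_obs)):
            count += 1
        done += 1
    return PermutationResult(
        p=(1 + count) / (1 + n_perms),
        n_perms=n_perms,
        exhaustive=False,
        n_redrawn=redrawn,
    )


def map_discriminant(
    w: np.ndarray, model: PCAModel
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project the loading-space discriminant into shape space.

    ``w`` (length m <= r) is zero-padded to r, then ``w_hat = E @ w_tilde``
    with E the orthonormal component matrix; ``arrows`` is ``w_hat``
    reshaped (k, 3).  A display scale for the arrows is presentation
    metadata and deliberately not applied here.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size > model.r:
        raise ValueError(f"w has {w.size} entries but the model has rank {model.r}")
    w_tilde = np.zeros(model.r)
    w_tilde[: w.size] = w
    w_hat = model.components @ w_tilde
    return w_hat, w_hat.reshape(-1, 3)


def _deviations(x: np.ndarray, center: str) -> np.ndarray:
    if center == "mean":
        c = x.mean(axis=0)
    elif center == "median":
        c = np.median(x, axis=0)  # coordinate-wise median
    else:
        raise ValueError(f"unknown center {center!r}")
    return np.linalg.norm(x - c, axis=1)


def _levene_stat(da: np.ndarray, db: np.ndarray) -> float:
    """|t| of the pooled-variance two-sample t on the deviations."""
    na, nb = len(da), len(db)
    sp2 = ((da - da.mean()) ** 2).sum() + ((db - db.mean()) ** 2).sum()
    sp2 /= na + nb - 2
    if sp2 <= 0:
        return 0.0
    return float(
        abs(da.mean() - db.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    )


def levene_tests(
    a: np.ndarray,
    b: np.ndarray,
    n_perms: int = 20000,
    seed: int = 0,
) -> LeveneResult:
    """Multivariate Levene battery on m-dimensional loadings.

    Each observation's deviation is its Euclidean distance from its own
    group's center (mean, or coordinate-wise median for the robust
    variant); the statistic is the pooled-variance two-sample t on the
    deviations.  Parametric p uses the t distribution on N - 2 dof; the
    randomized variants permute group labels of the pooled deviations with
    the ``(1 + count) / (1 + B)`` convention (exhaustive when feasible).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 observations")
    rng = np.random.default_rng(seed)
    out = {}
    for center in ("mean", "median"):
        da = _deviations(a, center)
        db = _deviations(b, center)
        allzero = np.all(da == 0) and np.all(db == 0)
        t = _levene_stat(da, db)
        if allzero:
            out[center] = 1.0
            out[f"randomized_{center}"] = 1.0
            continue
        out[center] = float(2.0 * sps.t.sf(t, na + nb - 2))
        pooled = np.concatenate([da, db])
        total = comb(na + nb, na)
        if total <= n_perms:
            count = 0
            for combo in itertools.combinations(range(na + nb), na):
                ia = np.array(combo)
                ib = np.setdiff1d(np.arange(na + nb), ia, assume_unique=True)
                if _levene_stat(pooled[ia], pooled[ib]) >= t - 1e-12:
                    count += 1
            out[f"randomized_{center}"] = count / total
        else:
            count = 0
            for _ in range(n_perms):
                perm = rng.permutation(na + nb)
                if _levene_stat(pooled[perm[:na]], pooled[perm[na:]]) >= t - 1e-12:
                    count += 1
            out[f"randomized_{center}"] = (1 + count) / (1 + n_perms)
    return LeveneResult(
        mean_p=out["mean"],
        median_p=out["median"],
        randomized_mean_p=out["randomized_mean"],
        randomized_median_p=out["randomized_median"],
        n_perms=n_perms,
    )


def group_mean_shape(sm: ShapeMatrix, group: str) -> np.ndarray:
    """Coordinate-wise mean of one group's configurations, as (k, 3)."""
    mask = sm.groups == group
    if not mask.any():
        raise ValueError(f"empty group {group!r}")
    return sm.X[mask].mean(axis=0).reshape(-1, 3)


def compare_groups(
    loadings_a: np.ndarray,
    loadings_b: np.ndarray,
    model: PCAModel,
    m: int,
    names: tuple[str, str] = ("a", "b"),
    n_perms: int = 20000,
    seed: int = 0,
    with_levene: bool = True,
) -> GroupComparison:
    """Full pairwise comparison on the first ``m`` loading columns."""
    a = np.atleast_2d(loadings_a)[:, :m]
    b = np.atleast_2d(loadings_b)[:, :m]
    t2, w = hotelling_t2(a, b)
    p_par = parametric_p(t2, a.shape[0], b.shape[0], m)
    perm = permutation_p(a, b, n_perms=n_perms, seed=seed)
    w_hat, arrows = map_discriminant(w, model)
    lev = (
        levene_tests(a, b, n_perms=n_perms, seed=seed + 1)
        if with_levene
        else None
    )
    return GroupComparison(
        group_a=names[0],
        group_b=names[1],
        n_a=a.shape[0],
        n_b=b.shape[0],
        m=m,
        t2=t2,
        parametric_p=p_par,
        permutation_p=perm.p,
        n_perms=perm.n_perms,
        permutation_exhaustive=perm.exhaustive,
        w=w,
        w_hat=w_hat,
        arrows=arrows,
        levene=lev,
    )
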