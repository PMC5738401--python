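"""Shape-space construction: normalization, optional Procrustes rotation,
PCA via the dual eigenproblem, and parallel analysis for mode retention.

Every configuration is translated to zero centroid and divided by the RMS
distance of its points to the centroid, so scale is removed and recorded
separately.  PCA is fit on the n x 3k matrix of normalized rows; with
n << 3k the eigenproblem is solved in the n x n dual space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShapeMatrix",
    "PCAModel",
    "center_and_scale",
    "procrustes_rotate",
    "fit_pca",
    "parallel_analysis",
    "reconstruct_at_sd",
]


@dataclass
class ShapeMatrix:
    """n x 3k matrix of normalized configurations plus the normalization record."""

    X: np.ndarray                    # (n, 3k)
    groups: np.ndarray               # (n,) labels
    centroids: np.ndarray            # (n, 3) removed translations
    scales: np.ndarray               # (n,) removed RMS scales
    rotations: np.ndarray | None = None  # (n, 3, 3) applied rotations, if any

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1] // 3

    def points(self, row: int) -> np.ndarray:
        return self.X[row].reshape(-1, 3)

    def rows_for(self, *group_names: str) -> "ShapeMatrix":
        mask = np.isin(self.groups, list(group_names))
        return ShapeMatrix(
            X=self.X[mask],
            groups=self.groups[mask],
            centroids=self.centroids[mask],
            scales=self.scales[mask],
            rotations=None if self.rotations is None else self.rotations[mask],
        )


@dataclass
class PCAModel:
    mean: np.ndarray          # (3k,)
    components: np.ndarray    # (3k, r), orthonormal columns
    eigenvalues: np.ndarray   # (r,), descending
    loadings: np.ndarray      # (n, r)
    m: int = 0                # retained mode count (set by parallel analysis)

    @property
    def r(self) -> int:
        return self.components.shape[1]

    def variance_share(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else np.zeros_like(self.eigenvalues)


def center_and_scale(
    positions: np.ndarray, groups=None
) -> ShapeMatrix:
    """Normalize an (n, k, 3) particle array to zero centroid and unit RMS
    point-to-centroid distance per configuration.

    Raises
    ------
    ValueError
        If any configuration has all points coincident (zero scale).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("positions must have shape (n, k, 3)")
    n, k, _ = pos.shape
    if k < 2:
        raise ValueError("need k >= 2 points per configuration")
    cents = pos.mean(axis=1)
    centered = pos - cents[:, None, :]
    scales = np.sqrt(np.einsum("nkc,nkc->n", centered, centered) / k)
    if np.any(scales <= 0):
        bad = int(np.argmin(scales))
        raise ValueError(f"configuration {bad} has zero scale (coincident points)")
    normed = centered / scales[:, None, None]
    if groups is None:
        groups = np.array(["all"] * n)
    return ShapeMatrix(
        X=normed.reshape(n, 3 * k),
        groups=np.asarray(groups),
        centroids=cents,
        scales=scales,
    )


def procrustes_rotate(
    sm: ShapeMatrix, enable: bool = True, max_iter: int = 100, tol: float = 1e-8
) -> ShapeMatrix:
    """Generalized Procrustes rotation to the iteratively re-estimated mean
    (rotation only — no scaling, no reflection).  With ``enable=False`` the
    input is returned unchanged (bit-identical X).
    """
    if not enable:
        return sm
    n, k = sm.n, sm.k
    pts = sm.X.reshape(n, k, 3).copy()
    rots = np.tile(np.eye(3), (n, 1, 1))
    mean = pts[0].copy()
    for _ in range(max_iter):
        new_pts = np.empty_like(pts)
        for a in range(n):
            r = _kabsch(pts[a], mean)
            new_pts[a] = pts[a] @ r.T
            rots[a] = r @ rots[a]
        pts = new_pts
        new_mean = pts.mean(axis=0)
        change = float(np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-30))
        mean = new_mean
        if change < tol:
            break
    return ShapeMatrix(
        X=pts.reshape(n, 3 * k),
        groups=sm.groups,
        centroids=sm.centroids,
        scales=sm.scales,
        rotations=rots,
    )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R with R @ src_i ~= dst_i (no reflection)."""
    h = src.T @ dst
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    return vt.T @ s @ u.T


def fit_pca(sm: ShapeMatrix, rank_tol: float = 1e-12) -> PCAModel:
    """PCA of the shape matrix via the n x n dual eigenproblem.

    Eigenvalues are those of the sample covariance (divisor n - 1); rank
    is at most n - 1.  Reconstruction ``mean + loadings @ components.T``
    reproduces X exactly when all modes are kept.
    """
    n = sm.n
    if n < 3:
        raise ValueError("PCA needs at least 3 configurations")
    mu = sm.X.mean(axis=0)
    xc = sm.X - mu
    c = xc @ xc.T / (n - 1)
    lam, u = np.linalg.eigh(c)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]
    lam = np.maximum(lam, 0.0)
    keep = lam > rank_tol * max(lam.max(), 1.0)
    keep[min(n - 1, len(keep)):] = False
    r = int(keep.sum())
    if r == 0:
        return PCAModel(
            mean=mu,
            components=np.zeros((sm.X.shape[1], 0)),
            eigenvalues=np.zeros(0),
            loadings=np.zeros((n, 0)),
        )
    lam_r, u_r = lam[:r], u[:, :r]
    comps = xc.T @ u_r / np.sqrt((n - 1) * lam_r)
    loadings = xc @ comps
    return PCAModel(mean=mu, components=comps, eigenvalues=lam_r, loadings=loadings)


def parallel_analysis(
    sm: ShapeMatrix,
    n_draws: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Retained mode count by parallel analysis.

    Eigenvalues of the data are compared rank-by-rank against the chosen
    quantile of eigenvalues from ``n_draws`` synthetic datasets of matched
    dimensions filled with independent standard normal entries scaled to
    the data's per-column standard deviations.  ``m`` is the length of the
    leading run of data eigenvalues strictly exceeding their thresholds.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if not (0.5 < quantile < 1.0):
        raise ValueError("quantile must be in (0.5, 1)")
    n, d = sm.X.shape
    xc = sm.X - sm.X.mean(axis=0, keepdims=True)
    lam_data = _dual_eigvals(xc, n)
    col_sd = xc.std(axis=0, ddof=1)
    if not np.any(col_sd > 0):
        return 0
    rng = np.random.default_rng(seed)
    null_lams = np.empty((n_draws, len(lam_data)))
    for b in range(n_draws):
        z = rng.standard_normal((n, d)) * col_sd
        z -= z.mean(axis=0, keepdims=True)
        null_lams[b] = _dual_eigvals(z, n)[: len(lam_data)]
    thresh = np.quantile(null_lams, quantile, axis=0)
    exceeds = lam_data > thresh
    m = 0
    for flag in exceeds:
        if not flag:
            break
        m += 1
    return m


def _dual_eigvals(xc: np.ndarray, n: int) -> np.ndarray:
    lam = np.linalg.eigvalsh(xc @ xc.T / (n - 1))[::-1]
    return np.maximum(lam[: n - 1], 0.0)


def reconstruct_at_sd(model: PCAModel, mode: int, s: float) -> np.ndarray:
    """Configuration ``mean + s * sqrt(l_mode) * E_mode`` as a (k, 3) array.

    ``mode`` is 0-based and must index a retained mode (``mode < m`` when
    ``m`` is set, else ``mode < r``); ``|s| <= 5``.
    """
    limit = model.m if model.m > 0 else model.r
    if not (0 <= mode < limit):
        raise ValueError(f"mode {mode} out of range [0, {limit})")
    if abs(s) > 5:
        raise ValueError("|s| must be <= 5")
    vec = model.mean + s * np.sqrt(model.eigenvalues[mode]) * model.components[:, mode]
    return vec.reshape(-1, 3)
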