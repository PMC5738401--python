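"""Binary segmentation volumes and signed-distance implicit surfaces.

World-coordinate convention: ``world = origin + index * spacing`` with
0-based, cell-centered indices.  Signed distances are negative inside the
foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "BinaryVolume",
    "ImplicitSurface",
    "GridSDF",
    "SphereSDF",
    "PlaneSDF",
    "TriangleMesh",
    "ProjectionError",
    "mask_to_sdf",
    "project_to_surface",
    "extract_mesh",
]


class ProjectionError(RuntimeError):
    """Newton projection onto the zero level set failed to converge."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


@dataclass
class BinaryVolume:
    """A voxelized segmentation of one specimen.

    Parameters
    ----------
    grid : ndarray of shape (nx, ny, nz)
        Values exactly 0 or 1.
    spacing : (3,) array-like
        Strictly positive world units per voxel along each axis.
    origin : (3,) array-like
        World coordinates of voxel index (0, 0, 0).
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    def validate(self) -> None:
        """Check the full invariants (values 0/1, fg and bg present, margin)."""
        vals = np.unique(self.grid)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("grid values must be exactly 0/1")
        if not (self.grid.any() and (self.grid == 0).any()):
            raise ValueError("grid needs at least one foreground and one background voxel")
        g = self.grid
        if (
            g[0].any() or g[-1].any()
            or g[:, 0].any() or g[:, -1].any()
            or g[:, :, 0].any() or g[:, :, -1].any()
        ):
            raise ValueError("foreground touches the grid boundary")

    @property
    def foreground_volume(self) -> float:
        """Foreground voxel count times voxel volume, in world units cubed."""
        return float(self.grid.sum()) * float(np.prod(self.spacing))

    def foreground_centroid(self) -> np.ndarray:
        idx = np.argwhere(self.grid > 0)
        return self.origin + idx.mean(axis=0) * self.spacing


class ImplicitSurface:
    """Protocol for signed scalar fields with a zero level set.

    Subclasses implement :meth:`value` and :meth:`gradient` for batches of
    world points, a :meth:`centroid_hint` used to seed particles, and a
    :meth:`scale_hint` giving a characteristic radius.
    """

    def value(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def centroid_hint(self) -> np.ndarray:
        raise NotImplementedError

    def scale_hint(self) -> float:
        raise NotImplementedError


class SphereSDF(ImplicitSurface):
    """Analytic sphere signed distance, used as an oracle in tests."""

    def __init__(self, center=(0.0, 0.0, 0.0), radius: float = 1.0):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def value(self, points):
        p = np.atleast_2d(points) - self.center
        return np.linalg.norm(p, axis=-1) - self.radius

    def gradient(self, points):
        p = np.atleast_2d(points) - self.center
        r = np.linalg.norm(p, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(r > 0, p / r, 0.0)
        return g

    def centroid_hint(self):
        return self.center.copy()

    def scale_hint(self):
        return self.radius


class PlaneSDF(ImplicitSurface):
    """Analytic plane ``normal . (x - point) = 0``; flat-region oracle."""

    def __init__(self, normal=(0.0, 0.0, 1.0), point=(0.0, 0.0, 0.0), extent: float = 10.0):
        n = np.asarray(normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        self.point = np.asarray(point, dtype=float)
        self.extent = float(extent)

    def value(self, points):
        p = np.atleast_2d(points) - self.point
        return p @ self.normal

    def gradient(self, points):
        p = np.atleast_2d(points)
        return np.broadcast_to(self.normal, p.shape).copy()

    def centroid_hint(self):
        return self.point.copy()

    def scale_hint(self):
        return self.extent


@dataclass
class GridSDF(ImplicitSurface):
    """Signed distance sampled on a regular grid; negative inside.

    Values and gradients are trilinear interpolants; gradients come from
    central differences of ``phi`` so that value/gradient evaluations stay
    mutually consistent for Newton projection.  Interpolation is a single
    fused trilinear gather over (phi, gx, gy, gz) — this sits in the
    optimizer's innermost loop.  Queries outside the grid are clamped to
    the boundary cell.
    """

    phi: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    _fields: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        gx, gy, gz = np.gradient(self.phi, *self.spacing)
        self._fields = np.stack([self.phi, gx, gy, gz], axis=-1)

    def _interp_all(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        t = (p - self.origin) / self.spacing
        shape = np.array(self.phi.shape)
        t = np.clip(t, 0.0, shape - 1.000001)
        i0 = t.astype(np.int64)
        i0 = np.minimum(i0, shape - 2)
        f = t - i0
        g = 1.0 - f
        fl = self._fields
        x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
        x1, y1, z1 = x0 + 1, y0 + 1, z0 + 1
        out = (
            fl[x0, y0, z0] * (g[:, 0] * g[:, 1] * g[:, 2])[:, None]
            + fl[x1, y0, z0] * (f[:, 0] * g[:, 1] * g[:, 2])[:, None]
            + fl[x0, y1, z0] * (g[:, 0] * f[:, 1] * g[:, 2])[:, None]
            + fl[x0, y0, z1] * (g[:, 0] * g[:, 1] * f[:, 2])[:, None]
            + fl[x1, y1, z0] * (f[:, 0] * f[:, 1] * g[:, 2])[:, None]
            + fl[x1, y0, z1] * (f[:, 0] * g[:, 1] * f[:, 2])[:, None]
            + fl[x0, y1, z1] * (g[:, 0] * f[:, 1] * f[:, 2])[:, None]
            + fl[x1, y1, z1] * (f[:, 0] * f[:, 1] * f[:, 2])[:, None]
        )
        return out

    def value(self, points):
        return self._interp_all(points)[:, 0]

    def gradient(self, points):
        return self._interp_all(points)[:, 1:4]

    def centroid_hint(self):
        idx = np.argwhere(self.phi < 0)
        if idx.size == 0:
            raise ValueError("SDF has no interior (phi >= 0 everywhere)")
        return self.origin + idx.mean(axis=0) * self.spacing

    def scale_hint(self):
        vol = float((self.phi < 0).sum()) * float(np.prod(self.spacing))
        return (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def min_spacing(self) -> float:
        return float(self.spacing.min())


def mask_to_sdf(v: BinaryVolume, smoothing_sigma: float = 0.0) -> GridSDF:
    """Convert a binary volume to a signed Euclidean distance field.

    The field composes the exact inside/outside Euclidean distance
    transforms, shifted by half a voxel each so distances refer to the
    interface rather than the neighboring voxel center (a naive
    ``d_out - d_in`` has slope 2 at the first voxel ring).  Near the zero
    set the raw transform carries a voxel staircase that corrupts the
    level-set position and gradient, so the field is Gaussian-smoothed at
    one voxel there and blended back into the exact far field with
    distance — Gaussian smoothing is exact on planar distance fields, so
    the residual near-surface bias is curvature-sized.

    ``smoothing_sigma`` (world units, >= 0) additionally smooths the
    mask's antialiased level set (threshold 0.5) before re-distancing.

    Raises
    ------
    ValueError
        If the foreground is empty.
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    mask = v.grid > 0
    if not mask.any():
        raise ValueError("empty foreground")
    if smoothing_sigma > 0:
        f = ndimage.gaussian_filter(
            mask.astype(float), sigma=smoothing_sigma / v.spacing
        )
        mask2 = f >= 0.5
        if mask2.any() and (~mask2).any():
            mask = mask2
    h = float(v.spacing.min())
    d_out = ndimage.distance_transform_edt(~mask, sampling=v.spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=v.spacing)
    half = 0.5 * h
    phi0 = np.where(mask, -(d_in - half), d_out - half)
    phi_s = ndimage.gaussian_filter(phi0, sigma=1.0)  # one voxel per axis
    t = np.clip((np.abs(phi0) - 2.5 * h) / (2.0 * h), 0.0, 1.0)
    phi = (1.0 - t) * phi_s + t * phi0
    return GridSDF(phi=phi, spacing=v.spacing.copy(), origin=v.origin.copy())


def project_to_surface(
    x: np.ndarray,
    s: ImplicitSurface,
    tol: float,
    max_iter: int = 30,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Project points onto the zero level set by damped Newton iteration.

    Iterates ``x <- x - phi(x) * grad/|grad|^2`` until ``|phi| <= tol``.
    Points with a degenerate gradient (e.g. the exact center of a sphere)
    get a small deterministic nudge rather than silently diverging.

    Parameters
    ----------
    x : (3,) or (p, 3) array of world points.
    tol : positive convergence tolerance on ``|phi|``.

    Raises
    ------
    ProjectionError
        If any point fails to reach ``|phi| <= tol`` in ``max_iter`` steps.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    single = np.ndim(x) == 1
    pts = np.atleast_2d(np.asarray(x, dtype=float)).copy()
    nudge_rng = rng if rng is not None else np.random.default_rng(0)
    active = np.abs(s.value(pts)) > tol
    fused = getattr(s, "_interp_all", None)
    for _ in range(max_iter):
        if not active.any():
            break
        p = pts[active]
        if fused is not None:
            vg = fused(p)
            val, g = vg[:, 0], vg[:, 1:4]
        else:
            val = s.value(p)
            g = s.gradient(p)
        gn2 = np.einsum("ij,ij->i", g, g)
        bad = gn2 < 1e-12
        if bad.any():
            p[bad] = p[bad] + nudge_rng.normal(scale=tol, size=(bad.sum(), 3))
            val = s.value(p)
            g = s.gradient(p)
            gn2 = np.maximum(np.einsum("ij,ij->i", g, g), 1e-12)
        step = (val / gn2)[:, None] * g
        # damp steps larger than one characteristic length to stay stable
        norm = np.linalg.norm(step, axis=1)
        cap = max(abs(val).max(), tol) * 2.0
        big = norm > cap
        if big.any():
            step[big] *= (cap / norm[big])[:, None]
        pts[active] = p - step
        active = np.abs(s.value(pts)) > tol
    if active.any():
        resid = float(np.abs(s.value(pts[active])).max())
        raise ProjectionError(
            f"projection failed for {int(active.sum())} point(s), max |phi| = {resid:.3g}",
            residual=resid,
        )
    return pts[0] if single else pts


@dataclass
class TriangleMesh:
    """Triangle surface mesh in world coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def _edges(self) -> np.ndarray:
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.sort(e, axis=1)

    def euler_characteristic(self) -> int:
        nv = len(np.unique(self.faces))
        ne = len(np.unique(self._edges(), axis=0))
        nf = len(self.faces)
        return nv - ne + nf

    def is_watertight(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        _, counts = np.unique(self._edges(), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def cleaned(self, area_eps: float = 0.0) -> "TriangleMesh":
        """Drop degenerate faces and unreferenced vertices."""
        areas = self.face_areas()
        keep = self.faces[areas > area_eps]
        used = np.unique(keep)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[keep])


def extract_mesh(s: GridSDF, level: float = 0.0) -> TriangleMesh:
    """Extract the zero level set as a triangle mesh via marching cubes.

    Raises
    ------
    ValueError
        If ``phi`` has no zero crossing.
    """
    if s.phi.min() >= level or s.phi.max() <= level:
        raise ValueError("no zero crossing in the scalar field")
    verts, faces, _, _ = measure.marching_cubes(
        s.phi, level=level, spacing=tuple(s.spacing)
    )
    verts = verts + s.origin
    return TriangleMesh(verts, faces).cleaned()
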