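"""Synthetic populations of 3D segmentations with planted group effects.

The base family is a superellipsoid (configurable exponent), which has
flat-ish faces and edge-like features so that downstream correspondence is
exercised harder than by a plain ellipsoid.  Group effects are smooth,
radially supported bumps ("lateral_bump", "edge_inflection") whose
amplitude and angular extent are known, so recovery can be scored against
ground truth.  Amplitude 0 reproduces the null family exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from . import io as scio
from .volumes import BinaryVolume

__all__ = [
    "EffectSpec",
    "GroupSpec",
    "PopulationSpec",
    "GroundTruth",
    "RadialShape",
    "apply_effect",
    "effect_angle",
    "effect_support_mask",
    "generate_population",
    "write_population",
    "EFFECT_NAMES",
    "STRONG_AMPLITUDE",
]

EFFECT_NAMES = ("none", "lateral_bump", "edge_inflection")

#: Generator default for a "strong" planted effect (world units); chosen for
#: test power, not biological fidelity.
STRONG_AMPLITUDE = 1.5

# Bump center directions (unit vectors) per effect family.  "lateral_bump"
# is a symmetric broadening applied on BOTH lateral sides so the specimen
# centroid stays put; "edge_inflection" is one-sided.
_EFFECT_CENTERS = {
    "lateral_bump": np.array([0.0, 1.0, 0.0]),
    "edge_inflection": np.array([-0.8, 0.0, -0.6]) / np.linalg.norm([-0.8, 0.0, -0.6]),
}
_EFFECT_SYMMETRIC = {"lateral_bump": True, "edge_inflection": False}


def effect_angle(dirs: np.ndarray, effect_name: str) -> np.ndarray:
    """Angular distance of unit directions from the effect's center axis
    (to the nearer of the two centers for symmetric effects)."""
    c = _EFFECT_CENTERS[effect_name]
    cosang = np.clip(np.atleast_2d(dirs) @ c, -1.0, 1.0)
    if _EFFECT_SYMMETRIC[effect_name]:
        cosang = np.abs(cosang)
    return np.arccos(cosang)


def effect_support_mask(
    dirs: np.ndarray, effect_name: str, extent: float
) -> np.ndarray:
    """True for directions inside the planted effect's angular support."""
    return effect_angle(dirs, effect_name) < extent


@dataclass
class EffectSpec:
    """A named radial deformation with amplitude (world units) and angular extent."""

    name: str = "none"
    amplitude: float = 0.0
    extent: float = 0.9  # radians, half-angle of the support cone

    def __post_init__(self):
        if self.name not in EFFECT_NAMES:
            raise ValueError(
                f"unknown effect {self.name!r}; expected one of {EFFECT_NAMES}"
            )
        if not np.isfinite(self.amplitude):
            raise ValueError("effect amplitude must be finite")
        if not (0.0 < self.extent <= np.pi):
            raise ValueError("effect extent must be in (0, pi]")

    @property
    def center_direction(self) -> np.ndarray | None:
        return None if self.name == "none" else _EFFECT_CENTERS[self.name].copy()


@dataclass
class GroupSpec:
    """One population group: its size and the effect amplitude it carries."""

    name: str
    n: int
    amplitude: float = 0.0
    amplitude_sd: float = 0.0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError(f"group {self.name!r}: n must be positive")


@dataclass
class PopulationSpec:
    """Full recipe for a synthetic population; deterministic given ``seed``."""

    groups: list[GroupSpec]
    base_axes: tuple[float, float, float] = (8.0, 5.0, 3.0)
    exponent: float = 2.5
    within_group_sd: float = 0.05  # sd of log-axis lengths
    effect: str = "none"
    extent: float = 0.9
    voxel_spacing: float = 0.5
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    rotation_sd: float = 0.0  # radians; optional pose nuisance, default off
    seed: int = 0
    margin_voxels: int = 2

    def __post_init__(self):
        self.groups = [
            g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups
        ]
        if isinstance(self.grid_shape, int):
            self.grid_shape = (self.grid_shape,) * 3
        self.grid_shape = tuple(int(x) for x in self.grid_shape)
        self.base_axes = tuple(float(a) for a in self.base_axes)
        if any(a <= 0 for a in self.base_axes):
            raise ValueError("axis lengths must be strictly positive")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be strictly positive")
        if self.effect not in EFFECT_NAMES:
            raise ValueError(
                f"unknown effect {self.effect!r}; expected one of {EFFECT_NAMES}"
            )
        if self.within_group_sd < 0:
            raise ValueError("within_group_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generating parameters for one specimen."""

    specimen_id: str
    group: str
    axes: tuple[float, float, float]
    amplitude: float
    effect: str
    extent: float
    rotation: np.ndarray | None = None  # 3x3, applied to the base shape


@dataclass
class RadialShape:
    """Star-shaped implicit solid: inside iff ``|p| <= radius(p/|p|)``.

    The undeformed radius comes from a superellipsoid
    ``sum_i |u_i/a_i|^e = 1``; a planted effect adds a smooth (C^1) radial
    displacement supported within a cone of half-angle ``extent`` around the
    effect's center direction.
    """

    axes: tuple[float, float, float]
    exponent: float = 2.5
    effect: EffectSpec = field(default_factory=EffectSpec)
    rotation: np.ndarray | None = None

    def base_radius(self, dirs: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(dirs)
        a = np.asarray(self.axes, dtype=float)
        s = np.sum(np.abs(u / a) ** self.exponent, axis=-1)
        return s ** (-1.0 / self.exponent)

    def displacement(self, dirs: np.ndarray) -> np.ndarray:
        """Radial displacement of the surface along unit directions ``dirs``."""
        u = np.atleast_2d(dirs)
        eff = self.effect
        if eff.name == "none" or eff.amplitude == 0.0:
            return np.zeros(u.shape[0])
        ang = effect_angle(u, eff.name)
        d = np.zeros(u.shape[0])
        inside = ang < eff.extent
        # cos^2 profile: amplitude at the center, C^1-smoothly 0 at the rim
        d[inside] = eff.amplitude * np.cos(0.5 * np.pi * ang[inside] / eff.extent) ** 2
        return d

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        return self.base_radius(dirs) + self.displacement(dirs)

    def max_radius(self) -> float:
        return float(max(self.axes) + max(self.effect.amplitude, 0.0))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        if self.rotation is not None:
            p = p @ self.rotation  # rotate points into body frame (R^T applied)
        r = np.linalg.norm(p, axis=-1)
        out = np.zeros(len(p), dtype=bool)
        nz = r > 0
        u = p[nz] / r[nz, None]
        out[nz] = r[nz] <= self.radius(u)
        out[~nz] = True
        return out

    def surface_points(self, dirs: np.ndarray) -> np.ndarray:
        """Exact surface points along unit directions (world frame)."""
        u = np.atleast_2d(dirs)
        pts = u * self.radius(u)[:, None]
        if self.rotation is not None:
            pts = pts @ self.rotation.T
        return pts

    def voxelize(
        self, spacing: float, grid_shape: tuple[int, int, int]
    ) -> BinaryVolume:
        """Sample the implicit inequality at voxel centers of a centered grid."""
        shape = np.asarray(grid_shape, dtype=int)
        origin = -(shape - 1) / 2.0 * spacing
        axes_coords = [origin[d] + np.arange(shape[d]) * spacing for d in range(3)]
        xx, yy, zz = np.meshgrid(*axes_coords, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        grid = self.contains(pts).reshape(tuple(shape)).astype(np.uint8)
        return BinaryVolume(grid, np.full(3, float(spacing)), origin)


def apply_effect(shape: RadialShape, effect: EffectSpec) -> RadialShape:
    """Return a copy of ``shape`` carrying ``effect`` as its deformation."""
    return RadialShape(
        axes=shape.axes,
        exponent=shape.exponent,
        effect=effect,
        rotation=None if shape.rotation is None else shape.rotation.copy(),
    )


def generate_population(
    spec: PopulationSpec,
) -> tuple[list[BinaryVolume], list[GroundTruth]]:
    """Generate one volume + ground-truth record per specimen.

    Each foreground is a single 26-connected component with no interior
    holes; the grid keeps at least ``spec.margin_voxels`` of background on
    every face.  Fully deterministic given ``spec.seed``.

    Raises
    ------
    ValueError
        If the grid is too small for the requested axes + amplitude,
        naming the offending specimen.
    """
    rng = np.random.default_rng(spec.seed)
    volumes: list[BinaryVolume] = []
    truths: list[GroundTruth] = []
    half_extent = (
        (np.asarray(spec.grid_shape) - 1) / 2.0 - spec.margin_voxels
    ) * spec.voxel_spacing
    for grp in spec.groups:
        for j in range(grp.n):
            sid = f"{grp.name}_{j:03d}"
            log_jit = rng.normal(0.0, spec.within_group_sd, size=3)
            axes = tuple(a * float(np.exp(e)) for a, e in zip(spec.base_axes, log_jit))
            if grp.amplitude_sd > 0:
                amp = float(grp.amplitude + rng.normal(0.0, grp.amplitude_sd))
            else:
                amp = float(grp.amplitude)
            rot = None
            if spec.rotation_sd > 0:
                rotvec = rng.normal(0.0, spec.rotation_sd, size=3)
                rot = Rotation.from_rotvec(rotvec).as_matrix()
            eff = EffectSpec(
                name=spec.effect if amp != 0.0 else spec.effect,
                amplitude=amp,
                extent=spec.extent,
            )
            shape = RadialShape(
                axes=axes, exponent=spec.exponent, effect=eff, rotation=rot
            )
            if shape.max_radius() > float(half_extent.min()):
                raise ValueError(
                    f"grid too small for specimen {sid}: "
                    f"max radius {shape.max_radius():.3g} exceeds usable "
                    f"half-extent {half_extent.min():.3g}"
                )
            vol = shape.voxelize(spec.voxel_spacing, spec.grid_shape)
            _check_topology(vol, sid)
            volumes.append(vol)
            truths.append(
                GroundTruth(
                    specimen_id=sid,
                    group=grp.name,
                    axes=axes,
                    amplitude=amp,
                    effect=spec.effect,
                    extent=spec.extent,
                    rotation=rot,
                )
            )
    return volumes, truths


def _check_topology(vol: BinaryVolume, sid: str) -> None:
    vol.validate()
    _, n_fg = ndimage.label(vol.grid, structure=np.ones((3, 3, 3), dtype=int))
    if n_fg != 1:
        raise ValueError(f"specimen {sid}: foreground has {n_fg} components")
    _, n_bg = ndimage.label(1 - vol.grid)  # 6-connectivity for background
    if n_bg != 1:
        raise ValueError(f"specimen {sid}: foreground encloses cavities")


def write_population(
    outdir: str | Path,
    volumes: list[BinaryVolume],
    truths: list[GroundTruth],
    fmt: str = "nrrd",
) -> Path:
    """Write volumes plus a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol, gt in zip(volumes, truths):
        fname = f"{gt.specimen_id}.{fmt}"
        scio.write_volume(outdir / fname, vol)
        rows.append(
            {
                "specimen_id": gt.specimen_id,
                "group": gt.group,
                "axis_a": gt.axes[0],
                "axis_b": gt.axes[1],
                "axis_c": gt.axes[2],
                "effect": gt.effect,
                "amplitude": gt.amplitude,
                "extent": gt.extent,
                "path": fname,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
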