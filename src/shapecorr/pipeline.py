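"""End-to-end driver: synth -> SDF -> correspondence -> normalization ->
per-comparison PCA + parallel analysis -> pairwise group tests -> exports.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so a rerun with the same config produces a
byte-identical report.  PCA and parallel analysis are fit per comparison
on the union of the two groups being compared, and the discriminant arrows
point from the second (reference) group toward the first (contrast) group.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import RBFInterpolator

from . import io as scio
from .correspond import OptimizerConfig, ParticleSystem, optimize
from .shapespace import (
    PCAModel,
    ShapeMatrix,
    center_and_scale,
    fit_pca,
    parallel_analysis,
    procrustes_rotate,
    reconstruct_at_sd,
)
from .stats import GroupComparison, compare_groups, group_mean_shape
from .synth import GroundTruth, PopulationSpec, generate_population
from .volumes import BinaryVolume, extract_mesh, mask_to_sdf

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "export_visuals",
    "stage_seed",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 32-bit seed for a named stage."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little")


@dataclass
class PipelineConfig:
    synth: PopulationSpec | None = None
    manifest: str | None = None          # alternative: CSV manifest of volumes
    k_target: int = 128
    smoothing_sigma: float | None = None  # world units; default 1 voxel
    align: bool = True                    # generalized Procrustes rotation
    pa_draws: int = 500
    pa_quantile: float = 0.95
    n_perms: int = 20000
    reference: str | None = None          # arrows point reference -> contrast
    comparisons: list[tuple[str, str]] | None = None  # (contrast, reference)
    master_seed: int = 0
    optimizer: dict = field(default_factory=dict)
    write_meshes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = PopulationSpec(**raw["synth"])
        if "comparisons" in raw and raw["comparisons"] is not None:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        return cls(**raw)

    def effective_comparisons(self, group_names: list[str]) -> list[tuple[str, str]]:
        if self.comparisons is not None:
            for a, b in self.comparisons:
                for g in (a, b):
                    if g not in group_names:
                        raise ValueError(f"comparison references unknown group {g!r}")
            return list(self.comparisons)
        ref = self.reference if self.reference is not None else group_names[0]
        if ref not in group_names:
            raise ValueError(f"reference group {ref!r} not in population")
        others = [g for g in group_names if g != ref]
        pairs = [(g, ref) for g in others]
        pairs += [(b, a) for i, a in enumerate(others) for b in others[i + 1:]]
        return pairs


@dataclass
class PipelineResult:
    report: dict
    shape_matrix: ShapeMatrix
    particle_system: ParticleSystem
    truths: list[GroundTruth]
    volumes: list[BinaryVolume]
    models: dict[tuple[str, str], PCAModel]
    comparisons: dict[tuple[str, str], GroupComparison]
    submatrices: dict[tuple[str, str], ShapeMatrix]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_manifest(manifest: str | Path):
    df = pd.read_csv(manifest)
    base = Path(manifest).parent
    vols, truths = [], []
    for _, row in df.iterrows():
        vols.append(scio.read_volume(base / row["path"]))
        truths.append(
            GroundTruth(
                specimen_id=str(row["specimen_id"]),
                group=str(row["group"]),
                axes=(row.get("axis_a", 0.0), row.get("axis_b", 0.0), row.get("axis_c", 0.0)),
                amplitude=float(row.get("amplitude", 0.0)),
                effect=str(row.get("effect", "none")),
                extent=float(row.get("extent", 0.0)),
            )
        )
    return vols, truths


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run the full workflow.  When ``outdir`` is given, writes the JSON
    report, CSV tables, particle files, and visualization exports there;
    partial outputs are retained if a stage fails."""
    # ---- input population
    if cfg.synth is not None:
        spec = dataclasses.replace(
            cfg.synth, seed=stage_seed(cfg.master_seed, "synth")
        )
        try:
            volumes, truths = generate_population(spec)
        except ValueError as exc:
            raise PipelineStageError("synth", str(exc)) from exc
    elif cfg.manifest is not None:
        volumes, truths = _load_manifest(cfg.manifest)
    else:
        raise ValueError("config needs either a synth spec or a manifest")
    groups = np.array([t.group for t in truths])
    group_names = list(dict.fromkeys(groups.tolist()))

    # ---- signed distance fields
    sigma = (
        cfg.smoothing_sigma
        if cfg.smoothing_sigma is not None
        else float(volumes[0].spacing.min())
    )
    surfaces = []
    for t, v in zip(truths, volumes):
        try:
            surfaces.append(mask_to_sdf(v, smoothing_sigma=sigma))
        except ValueError as exc:
            raise PipelineStageError("sdf", f"specimen {t.specimen_id}: {exc}") from exc

    # ---- correspondence
    opt_cfg = OptimizerConfig(
        k_target=cfg.k_target,
        seed=stage_seed(cfg.master_seed, "correspond"),
        **cfg.optimizer,
    )
    ps = optimize(surfaces, opt_cfg)

    # ---- normalization
    sm = center_and_scale(ps.positions, groups)
    sm = procrustes_rotate(sm, enable=cfg.align)

    # ---- per-comparison statistics
    pairs = cfg.effective_comparisons(group_names)
    models: dict[tuple[str, str], PCAModel] = {}
    comps: dict[tuple[str, str], GroupComparison] = {}
    subs: dict[tuple[str, str], ShapeMatrix] = {}
    rows = []
    for contrast, reference in pairs:
        tag = f"{contrast}_vs_{reference}"
        sub = sm.rows_for(contrast, reference)
        model = fit_pca(sub)
        m_pa = parallel_analysis(
            sub,
            n_draws=cfg.pa_draws,
            quantile=cfg.pa_quantile,
            seed=stage_seed(cfg.master_seed, f"pa:{tag}"),
        )
        n_a = int((sub.groups == contrast).sum())
        n_b = int((sub.groups == reference).sum())
        m = max(1, min(m_pa, model.r, n_a + n_b - 3))
        la = model.loadings[sub.groups == contrast]
        lb = model.loadings[sub.groups == reference]
        comp = compare_groups(
            la,
            lb,
            model,
            m,
            names=(contrast, reference),
            n_perms=cfg.n_perms,
            seed=stage_seed(cfg.master_seed, f"perm:{tag}"),
        )
        model.m = m
        models[(contrast, reference)] = model
        comps[(contrast, reference)] = comp
        subs[(contrast, reference)] = sub
        rows.append(
            {
                "comparison": tag,
                "contrast": contrast,
                "reference": reference,
                "n_contrast": n_a,
                "n_reference": n_b,
                "m_parallel_analysis": m_pa,
                "m_used": m,
                "t2": comp.t2,
                "parametric_p": comp.parametric_p,
                "permutation_p": comp.permutation_p,
                "n_perms": comp.n_perms,
                "permutation_exhaustive": comp.permutation_exhaustive,
                "levene_mean_p": comp.levene.mean_p,
                "levene_median_p": comp.levene.median_p,
                "levene_randomized_mean_p": comp.levene.randomized_mean_p,
                "levene_randomized_median_p": comp.levene.randomized_median_p,
            }
        )

    report = {
        "config": _config_record(cfg, sigma, opt_cfg),
        "n_specimens": len(volumes),
        "groups": {g: int((groups == g).sum()) for g in group_names},
        "k": ps.k,
        "optimizer_converged": ps.converged,
        "optimizer_warnings": ps.warnings,
        "comparisons": rows,
    }
    result = PipelineResult(
        report=report,
        shape_matrix=sm,
        particle_system=ps,
        truths=truths,
        volumes=volumes,
        models=models,
        comparisons=comps,
        submatrices=subs,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        pd.DataFrame(rows).to_csv(outdir / "comparisons.csv", index=False)
        from .correspond import save_particles

        save_particles(
            ps, outdir / "particles", ids=[t.specimen_id for t in truths]
        )
        export_visuals(result, outdir / "visuals", write_meshes=cfg.write_meshes)
    return result


def _config_record(cfg: PipelineConfig, sigma: float, opt_cfg: OptimizerConfig) -> dict:
    rec = dataclasses.asdict(cfg)
    if rec.get("synth") is not None and dataclasses.is_dataclass(cfg.synth):
        rec["synth"] = dataclasses.asdict(cfg.synth)
    rec["smoothing_sigma_effective"] = sigma
    rec["optimizer_effective"] = dataclasses.asdict(opt_cfg)
    if rec.get("comparisons") is not None:
        rec["comparisons"] = [list(c) for c in rec["comparisons"]]
    return rec


def export_visuals(
    result: PipelineResult, outdir: str | Path, write_meshes: bool = True
) -> list[Path]:
    """Write mode walks, group mean shapes, and discriminant arrow files.

    Per comparison and retained mode: point configurations at
    s in {-3, -2, -1, +1, +2, +3} (6m files).  Per comparison: both group
    mean point sets, a VTK polydata of the reference mean carrying the
    arrow vectors (reference -> contrast), and optionally a mean-shape
    mesh warped from a reference specimen by the mean correspondence
    displacement.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sm = result.shape_matrix
    for (contrast, reference), comp in result.comparisons.items():
        tag = f"{contrast}_vs_{reference}"
        model = result.models[(contrast, reference)]
        for mode in range(model.m):
            for s in (-3, -2, -1, 1, 2, 3):
                pts = reconstruct_at_sd(model, mode, float(s))
                name = f"modewalk_{tag}_mode{mode + 1}_s{s:+d}.particles"
                written.append(scio.write_points(outdir / name, pts))
        mean_ref = group_mean_shape(sm, reference)
        mean_con = group_mean_shape(sm, contrast)
        written.append(
            scio.write_points(outdir / f"mean_{tag}_{reference}.particles", mean_ref)
        )
        written.append(
            scio.write_points(outdir / f"mean_{tag}_{contrast}.particles", mean_con)
        )
        written.append(
            scio.write_vtk_polydata(
                outdir / f"arrows_{tag}.vtk",
                mean_ref,
                vectors=comp.arrows,
                vectors_name="discriminant",
            )
        )
        if write_meshes:
            written.append(
                _write_warped_mean_mesh(result, contrast, reference, outdir, tag)
            )
    return written


def _write_warped_mean_mesh(
    result: PipelineResult,
    contrast: str,
    reference: str,
    outdir: Path,
    tag: str,
) -> Path:
    """Mean-shape surface: a reference specimen's mesh carried into the
    normalized frame, warped by an RBF fit from that specimen's particles
    to the reference group's mean particles."""
    sm = result.shape_matrix
    idx = int(np.flatnonzero(sm.groups == reference)[0])
    surf = result.particle_system.surfaces[idx]
    mesh = extract_mesh(surf)
    verts = (mesh.vertices - sm.centroids[idx]) / sm.scales[idx]
    if sm.rotations is not None:
        verts = verts @ sm.rotations[idx].T
    src = sm.points(idx)
    dst = group_mean_shape(sm, reference)
    warp = RBFInterpolator(src, dst - src, kernel="thin_plate_spline", smoothing=1e-10)
    warped = verts + warp(verts)
    return scio.write_vtk_polydata(
        outdir / f"mean_mesh_{tag}_{reference}.vtk", warped, faces=mesh.faces
    )
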