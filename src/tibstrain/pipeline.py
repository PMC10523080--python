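"""End-to-end pipeline: synthetic cohort -> shape models -> screening ->
FE strain fields per speed -> masked shaft extraction -> permutation
statistics per retained PC.

Every stage is reproducible from the config and seed; a machine-readable
manifest (resolved config, package version, seeds, output hashes) is written
with the results.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .fesolve import (
    DEFAULT_LIGAMENT_STIFFNESS,
    DEFAULT_TIE_STIFFNESS,
    FactorizedSystem,
    apply_loads,
    build_system,
)
from .fieldstats import TFieldResult, permutation_critical_t, significance_map
from .loads import SPEEDS, generate_loadset
from .shapemodel import PointDistributionModel, ScreeningResult, cohort_point_sets, collinearity_screen
from .strainfield import (
    DEFAULT_BOUNDS,
    build_field_matrix,
    mask_attachments,
    periosteal_surface,
    select_shaft_surface,
)
from .synthgeom import MUSCLE_NAMES, Cohort, TemplateConfig, generate_cohort
from .vtkio import write_vtk_mesh, write_vtk_surface

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

DEFAULT_COMPONENTS = {"tibia": 6, "tibia_fibula": 7, "cortical_trabecular": 4}


class PipelineConfig(BaseModel):
    """Validated pipeline configuration.

    Defaults equal the study parameters wherever one exists: shaft window
    15-75%, masking radii 10 mm (soleus) / 5 mm (others), collinearity
    cutoff r = 0.6, alpha = 0.05, ligament stiffnesses 133/166/78/101 N/mm
    and the orthotropic moduli set in :mod:`tibstrain.fesolve`.
    """

    n_subjects: int = Field(12, ge=3)
    axial_sections: int = Field(12, ge=8)
    circumferential_sections: int = Field(10, ge=8)
    speeds: list[int] = [3, 4, 5]
    shaft_bounds: tuple[float, float] = DEFAULT_BOUNDS
    soleus_mask_radius_mm: float = Field(10.0, ge=0)
    other_mask_radius_mm: float = Field(5.0, ge=0)
    alpha: float = Field(0.05, gt=0, lt=0.5)
    n_permutations: int = Field(2000, ge=20)
    collinearity_cutoff: float = Field(0.6, gt=0)
    n_components: dict[str, int] = dict(DEFAULT_COMPONENTS)
    with_scaling: bool = False
    tie_stiffness: float = Field(DEFAULT_TIE_STIFFNESS, gt=0)
    ligament_stiffness: dict[str, float] = dict(DEFAULT_LIGAMENT_STIFFNESS)
    seed: int = 0
    write_vtk: bool = False

    @field_validator("speeds")
    @classmethod
    def _speeds_supported(cls, v):
        bad = [s for s in v if s not in SPEEDS]
        if bad or not v:
            raise ValueError(f"speeds must be a non-empty subset of {SPEEDS}")
        return v

    @field_validator("shaft_bounds")
    @classmethod
    def _bounds_valid(cls, v):
        lo, hi = v
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("shaft bounds must satisfy 0 <= lo <= hi <= 1")
        return v

    def mask_radii(self) -> dict[str, float]:
        return {m: (self.soleus_mask_radius_mm if m == "soleus"
                    else self.other_mask_radius_mm) for m in MUSCLE_NAMES}

    def template_config(self) -> TemplateConfig:
        return TemplateConfig(axial_sections=self.axial_sections,
                              circumferential_sections=self.circumferential_sections)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    models: dict[str, PointDistributionModel]
    screening: ScreeningResult
    fields: dict[int, "object"]            # speed -> FieldMatrix
    stats: dict[tuple[str, int, int], TFieldResult]  # (variant, pc, speed)
    summary: pd.DataFrame
    out_dir: Path | None = None


def _stage_synth(config: PipelineConfig) -> Cohort:
    return generate_cohort(config.n_subjects, seed=config.seed,
                           config=config.template_config())


def _stage_ssm(config: PipelineConfig, cohort: Cohort) -> dict[str, PointDistributionModel]:
    models = {}
    for variant, k in config.n_components.items():
        pts = cohort_point_sets(cohort, variant)
        models[variant] = PointDistributionModel(
            n_components=min(k, len(cohort) - 1),
            with_scaling=config.with_scaling, variant=variant).fit(pts)
    return models


def _stage_screen(config: PipelineConfig,
                  models: dict[str, PointDistributionModel]) -> ScreeningResult:
    scores = {v: m.scores_ for v, m in models.items()}
    pct = {v: m.pct_variance_ for v, m in models.items()}
    return collinearity_screen(scores, pct, cutoff=config.collinearity_cutoff)


def _stage_fields(config: PipelineConfig, cohort: Cohort) -> dict[int, "object"]:
    """FE solve per subject (one factorization, one RHS per speed) and
    assembly of the masked shaft field matrix per speed."""
    selection = select_shaft_surface(cohort.template, config.shaft_bounds)
    selection = mask_attachments(selection, cohort.landmarks, cohort.template,
                                 config.mask_radii())
    per_speed = {s: [] for s in config.speeds}
    for mesh, cov in zip(cohort.meshes, cohort.covariates):
        system = build_system(mesh, cohort.landmarks,
                              config.ligament_stiffness, config.tie_stiffness)
        fact = FactorizedSystem(system)
        for speed in config.speeds:
            loads = apply_loads(system, generate_loadset(speed, cov),
                                cohort.landmarks)
            per_speed[speed].append(fact.solve(loads))
    fields = {}
    for speed in config.speeds:
        fields[speed] = build_field_matrix(per_speed[speed], selection,
                                           meshes=cohort.meshes)
    return fields


def _stage_stats(config: PipelineConfig, models, screening, fields):
    rng = np.random.default_rng(config.seed)
    stats: dict[tuple[str, int, int], TFieldResult] = {}
    rows = []
    for variant, pc in screening.retained:
        score = models[variant].scores_[:, pc - 1]
        for speed in config.speeds:
            seed = int(rng.integers(2 ** 31))
            res = permutation_critical_t(fields[speed], score,
                                         alpha=config.alpha,
                                         n_perm=config.n_permutations,
                                         seed=seed)
            stats[(variant, pc, speed)] = res
            smap = significance_map(res)
            finite = np.isfinite(res.t)
            rows.append({
                "variant": variant, "pc": pc, "speed_m_s": speed,
                "critical_t": res.critical_t,
                "max_abs_t": float(np.abs(res.t[finite]).max()) if finite.any() else np.nan,
                "n_significant": smap["n_significant"],
                "n_positive": smap["n_positive"],
                "n_negative": smap["n_negative"],
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
                "seed": seed,
            })
    return stats, pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute synth -> ssm -> screen -> fe -> extract -> stats.

    When ``out_dir`` is given, writes the cohort manifest, score and
    screening tables, per-speed field matrices, the stats summary and a JSON
    manifest with config, versions, seeds and output hashes (VTK meshes and
    surface fields too when ``write_vtk`` is set).
    """
    t0 = time.time()
    cohort = _stage_synth(config)
    models = _stage_ssm(config, cohort)
    screening = _stage_screen(config, models)
    fields = _stage_fields(config, cohort)
    stats, summary = _stage_stats(config, models, screening, fields)
    result = PipelineResult(config=config, cohort=cohort, models=models,
                            screening=screening, fields=fields, stats=stats,
                            summary=summary)
    if out_dir is not None:
        result.out_dir = _write_outputs(result, Path(out_dir), time.time() - t0)
    return result


def _write_outputs(result: PipelineResult, out: Path, elapsed: float) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    config = result.config
    written: dict[str, str] = {}

    p = out / "cohort.csv"
    result.cohort.manifest().to_csv(p, index=False)
    written[p.name] = _sha256(p)

    score_frames = []
    for variant, model in result.models.items():
        df = pd.DataFrame(model.scores_,
                          columns=[f"{variant}_pc{i + 1}"
                                   for i in range(model.scores_.shape[1])])
        score_frames.append(df)
    p = out / "pc_scores.csv"
    pd.concat(score_frames, axis=1).to_csv(p, index=False)
    written[p.name] = _sha256(p)

    p = out / "screening.csv"
    rows = ([{"variant": v, "pc": i, "status": "retained",
              "partner": "", "abs_r": np.nan} for v, i in result.screening.retained]
            + [{"variant": d["variant"], "pc": d["pc"], "status": "removed",
                "partner": f"{d['partner'][0]}_pc{d['partner'][1]}",
                "abs_r": d["abs_r"]} for d in result.screening.removed])
    pd.DataFrame(rows).to_csv(p, index=False)
    written[p.name] = _sha256(p)

    for speed, fm in result.fields.items():
        p = out / f"field_speed{speed}.csv"
        pd.DataFrame(fm.values, index=fm.subject_ids,
                     columns=[f"elem{e}" for e in fm.element_ids]).to_csv(p)
        written[p.name] = _sha256(p)

    p = out / "stats_summary.csv"
    result.summary.to_csv(p, index=False)
    written[p.name] = _sha256(p)

    if config.write_vtk:
        write_vtk_mesh(out / "template.vtk", result.cohort.template)
        surf = periosteal_surface(result.cohort.template)
        for (variant, pc, speed), res in result.stats.items():
            fm = result.fields[speed]
            sel_mask = np.isin(surf.owners, fm.element_ids)
            idx = {e: i for i, e in enumerate(fm.element_ids)}
            t_face = np.zeros(len(surf.owners))
            sig_face = np.zeros(len(surf.owners), dtype=np.int64)
            for fi, owner in enumerate(surf.owners):
                if owner in idx:
                    t_face[fi] = res.t[idx[owner]]
                    sig_face[fi] = int(np.sign(res.t[idx[owner]])) if res.significant[idx[owner]] else 0
            write_vtk_surface(out / f"tfield_{variant}_pc{pc}_speed{speed}.vtk",
                              result.cohort.template, surf.faces,
                              {"t_value": t_face, "significant": sig_face,
                               "in_field": sel_mask.astype(np.int64)})

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "elapsed_s": round(elapsed, 2),
        "outputs_sha256": written,
        "retained_components": [list(t) for t in result.screening.retained],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
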