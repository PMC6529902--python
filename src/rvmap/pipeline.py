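"""End-to-end pipeline: simulate -> phenotype -> stress -> spm -> survival.

One JSON-serialisable configuration drives the whole run; every stage writes
its outputs plus a manifest recording the configuration hash, the global
seed, package versions and the SHA-256 of every file produced, so a re-run
with the same configuration reproduces every stochastic output exactly.
Stages whose outputs already exist (matching configuration hash) are not
recomputed on a partial re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .mesh import (SurfaceMesh, VentricularShell, cavity_volume,
                   compute_curvature, compute_excursion, compute_wall_thickness,
                   inner_radius, relative_wall_thickness, shape_deviation,
                   vertex_voronoi_areas)
from .simulate import (SimulationConfig, SyntheticPopulation, VertexFieldMatrix,
                       default_config, generate_population, make_template_context)
from .spm import (DEFAULT_COVARIATES, METABOLITE_EXTRA_COVARIATES,
                  mesh_adjacency_lists, run_spm_model, run_spm_models)
from .stress import StressInputs, compute_wall_stress
from .surv import fit_cox, stress_pc1
from . import io as rvio

logger = logging.getLogger("rvmap")

__all__ = ["SpmModelSpec", "SpmSettings", "SurvivalSettings", "StageToggles",
           "PipelineConfig", "run_pipeline"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpmModelSpec(_Model):
    phenotype: str = "wall_thickness_ED"
    predictor: str = "mpap"
    metabolite_model: bool = False    # adds creatinine + bilirubin covariates


class SpmSettings(_Model):
    models: list[SpmModelSpec] = Field(default_factory=lambda: [
        SpmModelSpec(phenotype="wall_thickness_ED", predictor="mpap"),
        SpmModelSpec(phenotype="wall_stress_ES", predictor="mpap"),
    ])
    n_permutations: int = 1000
    n_parcellations: int = 50
    K: Optional[int] = None           # default: vertex count // 20
    q: float = 0.05


class SurvivalSettings(_Model):
    covariates: list[str] = Field(default_factory=lambda: [
        "age", "sex", "bsa", "time_from_diagnosis", "ph_group"])


class StageToggles(_Model):
    simulate: bool = True
    phenotype: bool = True
    stress: bool = True
    spm: bool = True
    survival: bool = True


class PipelineConfig(_Model):
    stages: StageToggles = Field(default_factory=StageToggles)
    simulation: SimulationConfig = Field(default_factory=default_config)
    spm: SpmSettings = Field(default_factory=SpmSettings)
    survival: SurvivalSettings = Field(default_factory=SurvivalSettings)
    seed: int = 0
    log_level: str = "INFO"
    write_meshes: bool = False        # per-subject PLY output is bulky

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f".{stage}.done"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_done(out: Path, stage: str, cfg_hash: str) -> None:
    (out / f".{stage}.done").write_text(cfg_hash)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages into ``out_dir`` and return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the global seed overrides the simulation seed; normalise before hashing
    config = config.model_copy(update={
        "simulation": config.simulation.model_copy(update={"seed": config.seed})})
    cfg_hash = config.config_hash()

    logger.info("pipeline start (seed=%d, hash=%s)", config.seed, cfg_hash[:12])
    ctx = make_template_context(config.simulation.template, config.simulation.noise)
    pop: SyntheticPopulation | None = None
    fields: dict[str, VertexFieldMatrix] = {}
    table: pd.DataFrame | None = None

    # ---- simulate -------------------------------------------------------
    if config.stages.simulate:
        pop = generate_population(config.simulation, template=ctx)
        table = pop.table
        fields = dict(pop.fields)
        if not _stage_done(out, "simulate", cfg_hash):
            rvio.write_subject_table(out / "subjects.csv", table)
            rvio.write_shell(out / "meshes", ctx.shell)
            truth = {
                "log_hr_per_sd": pop.truth.log_hr_per_sd,
                "seed": pop.truth.seed,
                "beta_maps": {k: v.tolist() for k, v in pop.truth.beta_maps.items()},
                "effect_masks": {k: v.astype(int).tolist()
                                 for k, v in pop.truth.effect_masks.items()},
                "true_pc1": pop.truth.true_pc1.tolist(),
            }
            (out / "truth.json").write_text(json.dumps(truth))
            if config.write_meshes and pop.shells is not None:
                for shells in pop.shells:
                    for shell in shells.values():
                        rvio.write_shell(out / "meshes", shell)
            _mark_done(out, "simulate", cfg_hash)
        logger.info("simulate: %d subjects, %d vertices",
                    len(table), ctx.shell.endo.n_vertices)
    else:
        table = rvio.read_subject_table(out / "subjects.csv")

    # ---- phenotype (geometric recomputation from meshes) ----------------
    pheno_dir = out / "phenotypes"
    if config.stages.phenotype:
        pheno_dir.mkdir(exist_ok=True)
        if _stage_done(out, "phenotype", cfg_hash):
            for name in ("wall_thickness_ED", "wall_thickness_ES", "excursion",
                         "shape_deviation", "relative_wall_thickness"):
                path = pheno_dir / f"{name}.csv"
                if path.exists():
                    fields[name] = rvio.read_field_matrix(path, name=name)
        else:
            if pop is not None and pop.shells is not None:
                fields.update(_measure_phenotypes(pop, ctx))
            elif pop is not None:
                logger.info("phenotype: field mode (no meshes); using generator fields")
                fields["relative_wall_thickness"] = VertexFieldMatrix(
                    fields["wall_thickness_ED"].values.copy(),
                    "relative_wall_thickness", "mm",
                    fields["wall_thickness_ED"].subject_ids)
            for name, fm in fields.items():
                rvio.write_field_matrix(pheno_dir / f"{name}.csv", fm)
            _mark_done(out, "phenotype", cfg_hash)
        logger.info("phenotype: wrote %d field matrices", len(fields))

    # ---- stress ---------------------------------------------------------
    if config.stages.stress:
        stress_csv = pheno_dir / "wall_stress_ES.csv"
        if _stage_done(out, "stress", cfg_hash) and stress_csv.exists():
            fields["wall_stress_ES"] = rvio.read_field_matrix(
                stress_csv, name="wall_stress_ES", units="kN/m^2")
        else:
            if pop is not None and pop.shells is not None:
                fields["wall_stress_ES"] = _measure_stress(pop, ctx)
            # field mode: generator stress matrix already present
            rvio.write_field_matrix(pheno_dir / "wall_stress_ES.csv",
                                    fields["wall_stress_ES"])
            mean_stress = fields["wall_stress_ES"].values.mean(axis=0)
            rvio.write_vtk_polydata(out / "mean_wall_stress.vtk", ctx.shell.endo,
                                    {"mean_stress": mean_stress,
                                     "region": ctx.shell.region_labels})
            _mark_done(out, "stress", cfg_hash)
        logger.info("stress: median %.1f kN/m^2",
                    float(np.median(fields["wall_stress_ES"].values)))

    # ---- spm ------------------------------------------------------------
    spm_summary = None
    if config.stages.spm and not _stage_done(out, "spm", cfg_hash):
        adjacency = mesh_adjacency_lists(ctx.shell.endo)
        areas = vertex_voronoi_areas(ctx.shell.endo)
        results = []
        for i, spec in enumerate(config.spm.models):
            if spec.phenotype not in fields:
                raise RuntimeError(f"spm stage: phenotype {spec.phenotype!r} "
                                   "not produced by earlier stages")
            covs = list(DEFAULT_COVARIATES)
            if spec.metabolite_model:
                covs += list(METABOLITE_EXTRA_COVARIATES)
            res = run_spm_model(fields[spec.phenotype].values, table,
                                spec.predictor, ctx.shell.endo,
                                covariates=covs,
                                n_parcellations=config.spm.n_parcellations,
                                K=config.spm.K,
                                n_permutations=config.spm.n_permutations,
                                seed=config.seed + i,
                                adjacency=adjacency,
                                model_id=f"{spec.phenotype}~{spec.predictor}")
            results.append(res)
        run_spm_models(results, ctx.shell.free_wall_mask, areas, q=config.spm.q)
        spm_dir = out / "spm"
        spm_dir.mkdir(exist_ok=True)
        spm_summary = {}
        for res in results:
            tag = res.model_id.replace("~", "_vs_")
            pd.DataFrame({"vertex_id": np.arange(len(res.beta)),
                          "beta": res.beta, "p": res.p_consensus,
                          "significant": res.significant.astype(int)}
                         ).to_csv(spm_dir / f"{tag}.csv", index=False)
            rvio.write_vtk_polydata(spm_dir / f"{tag}.vtk", ctx.shell.endo,
                                    {"beta": res.beta,
                                     "significant": res.significant.astype(int)})
            spm_summary[res.model_id] = {
                "max_beta": res.max_beta,
                "area_percent": res.area_percent,
                "n_subjects": res.n_subjects,
            }
        (spm_dir / "summary.json").write_text(json.dumps(spm_summary, indent=1))
        _mark_done(out, "spm", cfg_hash)
        logger.info("spm: %d models", len(results))

    # ---- survival -------------------------------------------------------
    surv_summary = None
    if config.stages.survival:
        W = fields["wall_stress_ES"].values
        pc1 = stress_pc1(W)
        fit = fit_cox(pc1.scores, table, covariates=config.survival.covariates)
        surv_summary = {
            "hazard_ratio_per_sd": fit.hazard_ratio,
            "ci_95": [fit.ci_lower, fit.ci_upper],
            "p_value": fit.p_value,
            "n": fit.n, "n_events": fit.n_events,
            "pc1_variance_share": pc1.variance_share,
        }
        (out / "survival.json").write_text(json.dumps(surv_summary, indent=1))
        _mark_done(out, "survival", cfg_hash)
        logger.info("survival: HR %.3f per SD (p=%.3g)",
                    fit.hazard_ratio, fit.p_value)

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "versions": _versions(),
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(out.rglob("*"))
                    if p.is_file() and p.name != "manifest.json"
                    and not p.name.startswith(".")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _versions() -> dict[str, str]:
    import lifelines
    import scipy
    import statsmodels
    import trimesh as tm
    return {"rvmap": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "trimesh": tm.__version__, "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__}


def _measure_phenotypes(pop: SyntheticPopulation,
                        ctx) -> dict[str, VertexFieldMatrix]:
    """Recompute the per-vertex phenotypes geometrically from subject meshes."""
    assert pop.shells is not None
    ids = pop.table["subject_id"].tolist()
    n = len(ids)
    V = ctx.shell.endo.n_vertices
    wt_ed = np.empty((n, V))
    wt_es = np.empty((n, V))
    exc = np.empty((n, V))
    shape = np.empty((n, V))
    rel_wt = np.empty((n, V))
    v_template = ctx.cavity_volume_ml
    for i, shells in enumerate(pop.shells):
        ed, es = shells["ED"], shells["ES"]
        f_ed, _ = compute_wall_thickness(ed)
        f_es, _ = compute_wall_thickness(es)
        wt_ed[i] = f_ed.values
        wt_es[i] = f_es.values
        exc[i] = compute_excursion(ed.endo, es.endo).values
        shape[i] = shape_deviation(ed.endo, ctx.shell.endo).values
        rel_wt[i] = relative_wall_thickness(
            f_ed, cavity_volume(ed.endo), v_template).values
    return {
        "wall_thickness_ED": VertexFieldMatrix(wt_ed, "wall_thickness_ED", "mm", ids),
        "wall_thickness_ES": VertexFieldMatrix(wt_es, "wall_thickness_ES", "mm", ids),
        "excursion": VertexFieldMatrix(exc, "excursion", "mm", ids),
        "shape_deviation": VertexFieldMatrix(shape, "shape_deviation", "mm", ids),
        "relative_wall_thickness": VertexFieldMatrix(rel_wt, "relative_wall_thickness", "mm", ids),
    }


def _measure_stress(pop: SyntheticPopulation, ctx) -> VertexFieldMatrix:
    """Per-subject stress maps from the measured end-systolic geometry."""
    assert pop.shells is not None
    ids = pop.table["subject_id"].tolist()
    spap = pop.table["spap"].to_numpy()
    n = len(ids)
    V = ctx.shell.endo.n_vertices
    stress = np.empty((n, V))
    mask = np.zeros((n, V), dtype=bool)
    for i, shells in enumerate(pop.shells):
        es = shells["ES"]
        curv = compute_curvature(es.endo)
        radius, clamped = inner_radius(curv)
        wt, _ = compute_wall_thickness(es)
        sf = compute_wall_stress(StressInputs(float(spap[i]), radius, wt,
                                              degenerate_curvature=clamped))
        stress[i] = sf.stress.values
        mask[i] = sf.mask
    return VertexFieldMatrix(stress, "wall_stress_ES", "kN/m^2", ids, mask=mask)
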