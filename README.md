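# rvmap

3D phenotyping and statistical mapping of the right ventricle (RV) on
co-registered surface meshes.

In pulmonary hypertension (PH), the right ventricle first adapts to its
elevated afterload by hypertrophy and then decompensates through dilatation,
rising wall stress and functional decline. Studying that remodelling at the
population level requires more than global volumetry: it needs per-vertex
maps of wall geometry and load across hundreds of co-registered ventricles,
and inference machinery that can say *where* on the ventricle a haemodynamic
or biochemical covariate is associated with the phenotype while controlling
the multiplicity of thousands of correlated vertex-wise tests. `rvmap`
implements that analysis chain for researchers working with cardiac atlas
data: image-derived endocardial/epicardial shell meshes that share a template
triangulation, a subject table of clinical covariates, and (optionally)
survival follow-up.

## What it computes

**Per-vertex phenotypes** (`rvmap.mesh`) on endo/epi shell pairs in template
correspondence: wall thickness WT (symmetric normal-ray distance between the
surfaces), relative WT (WT rescaled by (V_template/V_subject)^(1/3), which
separates hypertrophy from dilatation), principal curvatures of the surface,
systolic excursion |x_ES − x_ED|, and signed shape deviation from a mean
template. Global indices (`rvmap.summaries`): RVEDV, RVESV, SV, RVEF, free-wall
mass (septum excluded by its template label), Mosteller BSA and the indexed
variants, and the ventricular mass index VMI = RVMI/LVMI.

**Wall stress** (`rvmap.stress`): a thick-walled Laplace law evaluated at
every vertex of the end-systolic shell,

    σ_v = 0.133 · sPAP · R_v / (2 WT_v) · (1 + WT_v / (2 R_v))   [kN/m²]

with sPAP the systolic pulmonary artery pressure (mmHg), R_v = 1/H_v the
inner (endocardial) radius of curvature (mm) and WT_v the end-systolic wall
thickness (mm). The bracketed correction keeps the formula valid for thick,
hypertrophied walls; it reduces to the Young–Laplace law as WT/R → 0.

**Statistical parametric mapping** (`rvmap.spm`): at every vertex an OLS
model of the phenotype on a predictor of interest (z-scored) adjusted for
age, sex, ethnicity, BSA, PH group and time from diagnosis (metabolite models
additionally for creatinine and bilirubin); the reported effect is the
standardized partial regression coefficient β. Inference uses parcellation
consensus: the mesh is split into K connected parcels grown from random
seeds, parcel-mean responses are tested with Freedman–Lane residual
permutation, parcel p-values are broadcast to member vertices, and the
consensus over many random parcellations (median) is corrected by
Benjamini–Hochberg FDR at 5% jointly across all models in the run.
Significant regions are summarised by max β and the % of RV free-wall area
reached.

**Survival** (`rvmap.surv`): the subjects × vertices wall-stress matrix is
reduced to its first principal component; a Cox proportional-hazards model
(Efron ties) tests the unit-SD PC1 score as a predictor of all-cause
mortality, adjusted for age, sex, BSA, time from diagnosis and PH group.

**Synthetic cohorts** (`rvmap.simulate`): because such imaging cohorts cannot
be redistributed, the package generates a fully synthetic stand-in — a
schematic half-ellipsoid RV template with inlet/outlet/apical/septal labels,
per-subject shells deformed by region-confined covariate effects plus
spatially correlated noise, metabolite levels coupled to the stress PC1,
and survival times with a planted hazard ratio — so every stage of the
analysis is testable against known ground truth.

## Worked example

```python
from rvmap import PipelineConfig, run_pipeline
from rvmap.simulate import TemplateSpec

cfg = PipelineConfig(seed=1)
cfg.simulation = cfg.simulation.model_copy(update={
    "n_subjects": 150, "template": TemplateSpec(n_vertices=1000)})
cfg.spm = cfg.spm.model_copy(update={"n_permutations": 500,
                                     "n_parcellations": 25})
run_pipeline(cfg, "run")
```

This simulates 150 subjects under the default study conditions (a planted
WT~mPAP association of β = 0.29 confined to the RV inlet, reduced excursion
with rising mPAP, and a mortality hazard ratio of 1.27 per SD of stress PC1),
measures all phenotypes geometrically from the subject meshes, and writes
`run/spm/summary.json`:

```json
{
 "wall_thickness_ED~mpap": {"max_beta": 0.427, "area_percent": 27.9},
 "wall_stress_ES~mpap":    {"max_beta": 0.863, "area_percent": 100.0}
}
```

— the inlet hypertrophy effect is recovered (max standardized β 0.43 over
27.9% of the free-wall area, the planted inlet region), and wall stress,
which is driven directly by pressure, is associated with mPAP across the
whole free wall. `run/survival.json` holds the Cox fit:

```json
{"hazard_ratio_per_sd": 1.14, "ci_95": [0.94, 1.39], "p_value": 0.17,
 "n": 150, "n_events": 97}
```

(a planted HR of 1.27 is not reliably significant at n = 150 — the
calibration tests recover it in expectation at n = 300 over replicates).
The median wall stress in this cohort is 34.1 kN/m². A command-line
interface mirrors the stages: `rvmap simulate|phenotype|stress|spm|survival|run-all`.

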