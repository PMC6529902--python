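# Methods

This note documents the models, numerical choices and known limitations of
`rvmap`. Everything quantitative stated here is computed by the test suite or
by `scripts/acceptance.py`; nothing is quoted from external data.

## Geometry on template meshes

All subjects share one template triangulation, so a phenotype is a vector
indexed by template vertex and a cohort is a subjects × vertices matrix.
Coordinates are in mm, volumes in mL (divergence-theorem integral over the
closed triangulation / 1000), pressures in mmHg.

**Wall thickness.** The wall-perpendicular distance between endocardium and
epicardium is approximated as the symmetric average of two directed
distances: from each endocardial vertex, the shortest positive ray hit on the
epicardial surface along ± the vertex normal, and vice versa from the
epicardium. Averaging the two directed fields approximates the distance
measured perpendicular to a mid-wall surface without constructing the
mid-wall explicitly, and makes the measure exactly symmetric under swapping
the surfaces. Rays are intersected by Möller–Trumbore over KD-tree-pruned
candidate faces (48 nearest face centroids), with a dense all-face retry and a
closest-point fallback (flagged) for pathological vertices. On concentric
spheres of radii 25/28 mm the recovered thickness is 3 mm to machine
precision; on nested ellipsoids it matches a brute-force dense ray-casting
oracle within 3%.

**Curvature.** Principal curvatures are estimated by the standard polyhedral
scheme: on every triangle the 2×2 second fundamental form is fitted by least
squares to the finite differences of the vertex normals along the three
edges; face tensors are rotated into each incident vertex's tangent plane
and averaged with mixed-Voronoi-area weights; the eigenvalues of the
averaged tensor are κ1 ≥ κ2. The sign convention is positive where the
surface is convex toward the cavity. Accuracy is limited by the vertex
normals, so normals (when not supplied analytically) are estimated by an
angle-weighted average followed by one local-quadric refinement pass — a
paraboloid fit over the one-ring whose gradient replaces the normal. This
removes the O(h) curvature bias that averaged normals leave at irregular
vertices; the icosphere error then falls monotonically with refinement
(max |H−1| ≈ 1e-3 at subdivision 2 down to 2e-5 at subdivision 5).

**Inner radius of curvature.** The stress law uses R = 1/H of the
end-systolic endocardium. Which curvature defines R is a modelling choice;
mean curvature is used because the thick-wall Laplace form is derived for a
spherical shell, where H = 1/R exactly. H is clamped below at 0.01/mm
(R capped at 100 mm) so flat or saddle-shaped patches cannot blow up the
stress; clamped vertices are flagged and excluded (masked) downstream.

**Wall stress.** σ = 0.133·sPAP·R/(2WT)·(1 + WT/(2R)) kN/m², evaluated
per vertex on end-systolic geometry only, with the subject's sPAP applied
uniformly (no intracavitary pressure gradient). Vertices with WT = 0 are
masked rather than infinite. The grouping of the formula is fixed by its
thin-wall limit: at WT/R = 0.01 it exceeds the Young–Laplace value by
exactly the factor 1 + WT/(2R) = 1.005.

**Other phenotypes.** Excursion is the per-vertex Euclidean distance between
phases; shape deviation is the subject−template displacement projected on the
template normal (positive outward); relative WT is WT·(V_template/V_subject)^(1/3),
exactly invariant under isotropic scaling. Free-wall myocardial mass uses
density 1.05 g/mL and removes the septal share of the epi−endo shell volume
by thickness-weighted vertex area, which is exact for uniform thickness.

## Synthetic study conditions

The generator is the package's stand-in for a PH imaging cohort and defines
the conditions under which the statistics are calibrated.

* **Template.** A closed, C1-smooth "half-ellipsoid with basal dome": the
  lower half of a 25/25/40 mm ellipsoid joined tangentially at its equator
  to a flat dome of height 10 mm, meshed by latitude rings (~2000 vertices
  by default; ~1000 in the calibration runs to keep runtimes at desk scale),
  with analytic normals and a 3 mm normal-offset epicardium. A flat-capped
  half-ellipsoid was rejected because its 90° rim makes normal-offset
  thickness ill-defined. Regions (inlet, outlet, apical/trabecular, septum)
  are contiguous azimuth/height sectors; "free wall" is everything
  non-septal.
* **Cohort.** Age ~ N(60.8, 15.9) yr, 47.1% female, BSA ~ N(1.86, 0.25) m²,
  mPAP ~ N(44.5, 13.2) mmHg (correlated 0.25 with age as confounding),
  ethnicity 79.5/4.5/6.4/9.6% and diagnostic groups 31.7/13.5/3.8/48.1/2.9% —
  the printed summary characteristics of a large PH CMR cohort. sPAP is not
  reported in such summaries; it is generated from the empirical relation
  mPAP ≈ 0.61·sPAP + 2 inverted, plus N(0, 5) mmHg noise.
* **Fields.** Per-vertex noise is graph-Laplacian-smoothed white noise on
  the template mesh (10 iterations, weight 0.8), rescaled to unit pointwise
  SD — spatial correlation without reference to embedding coordinates. A
  planted effect with standardized coefficient β on predictor z adds
  s·(β·z + √(1−β²)·ε) inside its region (s = 0.5 mm for WT, 1.5 mm
  excursion, 2 mm shape), so β is recovered asymptotically as the
  standardized partial coefficient. Age/sex/BSA load on all fields
  (γ = 0.15) as confounders. Wall thickness is floored at 0.5 mm; if more
  than 1% of entries would fall below the floor the configuration is
  rejected as unphysiological.
* **Stress and survival.** The stress matrix follows from the planted ES
  geometry and sPAP by the same Laplace formula the analysis applies. The
  mortality hazard is exponential (baseline median 40 months) times
  exp(logHR · PC1), where PC1 is the true leading component of the planted
  stress matrix; censoring is uniform on (0, c) with c solved by root
  finding so the expected censored fraction matches the configured 30%.
  Defaults plant logHR = log(1.27) per SD.
* **What the generator does not emulate:** real RV anatomy (crescent
  geometry, trabeculation), segmentation error, registration error,
  non-linear covariate effects, informative censoring, and missingness
  beyond the metabolomics-subset flag. Passing tests therefore demonstrate
  the correctness and calibration of the *analysis*, not the behaviour of
  the upstream imaging chain.

## Inference

* **Vertex-wise GLM.** OLS per vertex; response and predictor z-scored
  (ddof 1), covariates in native units; ethnicity and PH group dummy-coded
  against their most frequent level; complete-case per model. The β equals
  the explicit normal-equations solution to 1e-10 (tested).
* **Parcellation consensus.** K connected parcels (default V/20) grown by
  multi-source BFS from uniformly drawn seeds; parcel-mean response tested
  by Freedman–Lane residual permutation (permute reduced-model residuals,
  re-add reduced fits, recompute the standardized β) — unrestricted
  permutation is invalid with covariates. Two-sided p per parcel is
  (1+#{|t*| ≥ |t|})/(P+1); parcel p is broadcast to member vertices; the
  consensus over parcellations is the lower median. One permutation index
  set is drawn per run and shared across parcellations. Relabelling the
  subjects jointly leaves the observed statistics identical and the
  p-values equal up to permutation Monte-Carlo error (the sampled
  permutation set is conjugated, not identical).
* **Multiplicity.** BH step-up at q = 0.05 on the pooled p-vector of all
  models in the run ("corrected jointly"). The consensus median of
  positively dependent permutation p-values is conservative, and the
  smallest attainable p is 1/(P+1), so at desk scale the realised null FDR
  sits well below nominal: the 200-replicate null calibration
  (`scripts/acceptance.py`) yields 0% empirical FDR, versus the ≤5%
  requirement.
* **Region summaries.** Max signed β among significant free-wall vertices
  and the mixed-Voronoi-area share of the free wall reached; on a spherical
  cap fixture the area share matches the closed form (1−cosθ)/2 within 2%.
* **Survival.** PC1 of the vertex-centred (not standardized — stress shares
  units across vertices; a switch exists) stress matrix via SVD, sign-aligned
  with mean stress, scaled to unit SD so the hazard ratio is per SD and
  scale-free. Cox PH by partial likelihood with Efron ties; Wald CI.
  Ethnicity is deliberately absent from the survival adjustment set. The
  planted HR 1.27 is recovered with mean 1.29 over 200 replicates at
  n = 300 (within the [1.22, 1.32] acceptance band; the small excess is the
  usual finite-sample bias of the Cox MLE), and under the null the 95% CI
  covers 1 at the nominal rate.

## Numerical and reproducibility choices

* Every stochastic stage draws from `default_rng(SeedSequence([seed,
  crc32(stage)]))`; replicate seeds come from `SeedSequence.generate_state`.
  Two pipeline runs with one seed produce byte-identical outputs; CSV floats
  are written with `%.17g` and parsed with round-trip precision, and arrays
  fed to LAPACK are forced C-contiguous, since factorization results differ
  at ulp level between memory layouts.
* Calibration problem sizes (200 subjects × 1000 vertices, 500 permutations,
  25 parcellations, 200 replicates; survival at n = 300, 200 replicates) are
  the package's desk-scale defaults; all scale linearly if increased.
* Degenerate inputs: zero-area triangles are excluded from curvature and
  flagged; open meshes are rejected with the boundary-edge count; rank
  deficiency is reported with the collinear column names; zero-variance
  responses yield β = 0 rather than NaN; an empty significance mask reports
  max β as absent and area 0%.

## Limitations

The stress model is a local Laplace law, not finite-element mechanics; it
ignores fibre orientation, residual stress and regional material properties.
The schematic template means absolute phenotype values (volumes, areas) are
not anatomically meaningful — only the statistical behaviour is. Parcel
statistics use the parcel mean only; threshold-free cluster enhancement and
random-field approaches are out of scope, as are mixed models, time-dependent
covariates and competing risks.
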