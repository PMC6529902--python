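"""Vertex-wise GLM, parcellation, permutation consensus and FDR control."""

import numpy as np
import pandas as pd
import pytest

from rvmap.mesh import vertex_voronoi_areas
from rvmap.simulate import (EffectSpec, SimulationConfig, TemplateSpec,
                            generate_population)
from rvmap.spm import (bh_fdr, build_design, fit_vertexwise_glm,
                       mesh_adjacency_lists, permutation_consensus_test,
                       random_parcellation, run_spm_model, run_spm_models,
                       summarize_region)

from conftest import icosphere_mesh


def _toy_table(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "x": rng.standard_normal(n),
        "age": rng.normal(60, 15, n),
        "sex": rng.choice(["F", "M"], n),
        "ethnicity": rng.choice(["A", "B", "C"], n, p=[0.7, 0.2, 0.1]),
        "bsa": rng.normal(1.9, 0.2, n),
        "ph_group": rng.choice(["G1", "G2", "G3"], n),
        "time_from_diagnosis": rng.lognormal(3, 1, n),
    })


class TestVertexwiseGlm:
    def test_matches_bruteforce_ols_oracle(self):
        """Explicit normal-equations solve, vertex by vertex, at 1e-10."""
        n, V = 120, 50
        table = _toy_table(n, seed=1)
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((n, V)) + 0.4 * table["x"].to_numpy()[:, None]
        design = build_design(table, "x")
        beta, _ = fit_vertexwise_glm(Y, design)
        X = design.X
        for v in range(V):
            y = Y[:, v]
            yz = (y - y.mean()) / y.std(ddof=1)
            b = np.linalg.inv(X.T @ X) @ X.T @ yz
            assert abs(beta[v] - b[design.predictor_index]) < 1e-10

    def test_perfect_linear_response_gives_unit_beta(self):
        n = 80
        rng = np.random.default_rng(3)
        x = rng.standard_normal(n)
        table = pd.DataFrame({"x": x})
        Y = np.outer(2.5 * x + 1.0, np.ones(20))
        design = build_design(table, "x", covariates=())
        beta, _ = fit_vertexwise_glm(Y, design)
        np.testing.assert_allclose(beta, 1.0, atol=1e-10)

    def test_null_betas_are_sampling_noise_sized(self):
        n, V = 500, 300
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"x": rng.standard_normal(n)})
        Y = rng.standard_normal((n, V))
        design = build_design(table, "x", covariates=())
        beta, _ = fit_vertexwise_glm(Y, design)
        assert np.abs(beta).mean() <= 2.0 / np.sqrt(n)

    def test_collinear_design_rejected_with_names(self):
        table = _toy_table(60, seed=5)
        table["dup"] = table["age"] * 2.0
        with pytest.raises(ValueError, match="collinear|rank"):
            build_design(table, "x", covariates=("age", "dup"))

    def test_too_few_subjects_rejected(self):
        table = _toy_table(8, seed=6)
        with pytest.raises(ValueError, match="subjects"):
            build_design(table, "x")

    def test_complete_case_rows_dropped(self):
        table = _toy_table(100, seed=7)
        table.loc[3, "bsa"] = np.nan
        design = build_design(table, "x")
        assert design.n == 99
        assert 3 not in design.rows


class TestParcellation:
    def test_single_parcel_and_singletons(self):
        mesh = icosphere_mesh(10.0, 2)
        whole = random_parcellation(mesh, 1, seed=0)
        assert np.all(whole.parcel_of == 0)
        atoms = random_parcellation(mesh, mesh.n_vertices, seed=0)
        assert len(np.unique(atoms.parcel_of)) == mesh.n_vertices

    def test_deterministic_and_seed_sensitive(self):
        mesh = icosphere_mesh(10.0, 3)
        a = random_parcellation(mesh, 30, seed=11)
        b = random_parcellation(mesh, 30, seed=11)
        c = random_parcellation(mesh, 30, seed=12)
        np.testing.assert_array_equal(a.parcel_of, b.parcel_of)
        assert not np.array_equal(a.parcel_of, c.parcel_of)

    def test_parcels_are_connected_on_mesh_graph(self):
        mesh = icosphere_mesh(10.0, 3)
        parc = random_parcellation(mesh, 25, seed=2)
        adj = mesh_adjacency_lists(mesh)
        for k in range(parc.n_parcels):
            members = set(parc.members(k).tolist())
            assert members
            start = next(iter(members))
            seen = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w in members and w not in seen:
                        seen.add(int(w))
                        stack.append(int(w))
            assert seen == members


class TestBhFdr:
    def test_step_up_hand_enumeration_all_rejected(self):
        # thresholds i*q/m = .0125, .025, .0375, .05; p(4)=.04 <= .05
        mask = bh_fdr(np.array([0.005, 0.01, 0.03, 0.04]), q=0.05)
        assert mask.all()

    def test_step_up_hand_enumeration_none_rejected(self):
        # smallest p 0.02 > 1*0.05/3
        mask = bh_fdr(np.array([0.02, 0.8, 0.9]), q=0.05)
        assert not mask.any()

    def test_degenerate_inputs(self):
        assert not bh_fdr(np.ones(10), q=0.05).any()
        assert bh_fdr(np.array([]), q=0.05).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


@pytest.fixture(scope="module")
def planted(template_ctx):
    cfg = SimulationConfig(
        n_subjects=150, make_meshes=False,
        template=TemplateSpec(n_vertices=1000),
        effects=[EffectSpec(phenotype="wall_thickness", predictor="mpap",
                            region="inlet", beta=0.35)], seed=31)
    return generate_population(cfg, template=template_ctx)


class TestPermutationConsensus:
    def test_relabelling_invariance(self, template_ctx, planted):
        """Jointly permuting subjects leaves consensus p-values unchanged up
        to permutation Monte-Carlo error."""
        pop = planted
        Y = pop.fields["wall_thickness_ED"].values
        design = build_design(pop.table, "mpap")
        mesh = template_ctx.shell.endo
        kw = dict(n_parcellations=8, K=50, n_permutations=300, seed=3)
        out1 = permutation_consensus_test(Y, design, mesh, **kw)
        rng = np.random.default_rng(8)
        sigma = rng.permutation(len(Y))
        table2 = pop.table.iloc[sigma].reset_index(drop=True)
        design2 = build_design(table2, "mpap")
        out2 = permutation_consensus_test(Y[sigma], design2, mesh, **kw)
        # identical observed statistics; p-values equal within MC resolution
        np.testing.assert_allclose(out1["beta_parcel_mean"],
                                   out2["beta_parcel_mean"], atol=1e-10)
        close = np.abs(out1["p_consensus"] - out2["p_consensus"])
        assert np.median(close) < 2.0 / np.sqrt(300)

    def test_consensus_stability_across_parcellation_seeds(self, template_ctx, planted):
        pop = planted
        mesh = template_ctx.shell.endo
        areas = vertex_voronoi_areas(mesh)
        masks = []
        for seed in (101, 202):
            res = run_spm_model(pop.fields["wall_thickness_ED"].values,
                                pop.table, "mpap", mesh, n_parcellations=25,
                                K=50, n_permutations=400, seed=seed)
            run_spm_models([res], template_ctx.shell.free_wall_mask, areas)
            masks.append(res.significant)
        inter = np.sum(masks[0] & masks[1])
        dice = 2 * inter / (masks[0].sum() + masks[1].sum())
        assert dice >= 0.8

    def test_too_few_permutations_rejected(self, template_ctx, planted):
        design = build_design(planted.table, "mpap")
        with pytest.raises(ValueError):
            permutation_consensus_test(
                planted.fields["wall_thickness_ED"].values, design,
                template_ctx.shell.endo, n_permutations=50)


class TestRegionSummary:
    def test_full_mask_is_all_area(self):
        areas = np.ones(100)
        free = np.ones(100, dtype=bool)
        beta = np.linspace(-1, 1, 100)
        mx, pct = summarize_region(beta, np.ones(100, bool), free, areas)
        assert pct == 100.0
        assert mx == beta[np.argmax(np.abs(beta))]

    def test_empty_mask_reports_absent(self):
        mx, pct = summarize_region(np.ones(50), np.zeros(50, bool),
                                   np.ones(50, bool), np.ones(50))
        assert mx is None and pct == 0.0

    def test_max_beta_is_signed_extreme(self):
        beta = np.zeros(30)
        beta[7] = -0.42
        sig = np.zeros(30, bool)
        sig[5:10] = True
        mx, _ = summarize_region(beta, sig, np.ones(30, bool), np.ones(30))
        assert mx == -0.42

    def test_spherical_cap_area_fraction(self):
        """Voronoi-area share of a polar cap matches the closed-form cap
        area fraction (1 - cos(theta))/2 of the sphere."""
        mesh = icosphere_mesh(10.0, 4)
        areas = vertex_voronoi_areas(mesh)
        cos_theta = 0.6
        cap = mesh.vertices[:, 2] / 10.0 > cos_theta
        free = np.ones(mesh.n_vertices, bool)
        _, pct = summarize_region(np.ones(mesh.n_vertices), cap, free, areas)
        analytic = 100.0 * (1 - cos_theta) / 2.0
        assert pct == pytest.approx(analytic, rel=0.02)
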