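import numpy as np
import pytest
from scipy import stats

from mogsa import (
    SimulationConfig,
    compute_gss,
    exclude_components,
    fit_mfa,
    gss_significance,
    nmm_scores,
    preprocess_block,
    project_genesets,
    simulate_project,
    table_weights,
)
from mogsa.io_formats import AnnotationMatrix, OmicsBlock
from mogsa.preprocess import TableWeighting


def fitted_toy(rng, K=3, p=12, n=6, n_sets=4, set_size=3):
    blocks, anns = [], []
    names = [f"set{j}" for j in range(n_sets)]
    for k in range(K):
        v = rng.normal(size=(p, n))
        v -= v.mean(1, keepdims=True)
        b = OmicsBlock(f"b{k}", [f"b{k}_f{i}" for i in range(p)],
                       [f"s{j}" for j in range(n)], v)
        G = np.zeros((p, n_sets), dtype=np.int8)
        for j in range(n_sets):
            G[rng.choice(p, set_size, replace=False), j] = 1
        blocks.append(b)
        anns.append(AnnotationMatrix(b.name, list(b.feature_ids), names, G))
    w = table_weights(blocks, "mfa")
    return blocks, anns, w, fit_mfa(blocks, w)


class TestProjectGenesets:
    def test_combined_space_is_sum_of_block_spaces(self, rng):
        _, anns, _, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        np.testing.assert_allclose(
            space.W, sum(space.W_blocks[nm] for nm in model.block_names),
            atol=1e-12)

    def test_singleton_set_row_is_loading_row(self, rng):
        """A one-gene set's projection is that gene's loading row."""
        blocks, _, w, model = fitted_toy(rng, K=1, n_sets=1)
        b = blocks[0]
        G = np.zeros((b.n_features, 1), dtype=np.int8)
        G[4, 0] = 1
        ann = AnnotationMatrix(b.name, list(b.feature_ids), ["solo"], G)
        space = project_genesets(model, [ann], normalization="unit-sum")
        np.testing.assert_allclose(space.W[0],
                                   model.block_loadings[b.name][4], atol=1e-12)

    def test_unmapped_set_errors(self, rng):
        blocks, _, w, model = fitted_toy(rng, K=1, n_sets=1)
        b = blocks[0]
        empty = AnnotationMatrix(b.name, list(b.feature_ids), ["void"],
                                 np.zeros((b.n_features, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="void"):
            project_genesets(model, [empty])

    def test_feature_order_mismatch_errors(self, rng):
        blocks, anns, _, model = fitted_toy(rng, K=1)
        bad = AnnotationMatrix(anns[0].block_name,
                               anns[0].feature_ids[::-1],
                               anns[0].set_names, anns[0].G)
        with pytest.raises(ValueError, match="feature order"):
            project_genesets(model, [bad])


class TestComputeGSS:
    @pytest.mark.parametrize("trial", range(10))
    def test_full_rank_equals_naive_matrix_multiplication(self, trial):
        """SVD completeness: all components reproduce the direct product."""
        rng = np.random.default_rng(300 + trial)
        blocks, anns, w, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        Y = compute_gss(model, space,
                        components=list(range(model.n_components))).Y
        oracle = nmm_scores(blocks, anns, weighting=w)
        np.testing.assert_allclose(Y, oracle, atol=1e-8)

    def test_block_and_component_decompositions_sum_to_total(self, rng):
        _, anns, _, model = fitted_toy(rng)
        model = model.with_selected([0, 2])
        space = project_genesets(model, anns)
        res = compute_gss(model, space)
        np.testing.assert_allclose(sum(res.by_block.values()), res.Y,
                                   atol=1e-8)
        np.testing.assert_allclose(sum(res.by_component.values()), res.Y,
                                   atol=1e-8)

    def test_linearity_in_annotation_without_normalization(self, rng):
        blocks, anns, w, model = fitted_toy(rng, K=1, n_sets=2)
        b = blocks[0]
        G = anns[0].G
        merged = AnnotationMatrix(b.name, list(b.feature_ids), ["u", "v"], G)
        both = np.clip(G[:, [0]] + G[:, [1]], 0, 1)
        # use disjoint sets so the sum of indicators stays binary
        if not np.array_equal(both.ravel(), (G[:, 0] + G[:, 1])):
            G = np.zeros_like(G)
            G[:3, 0] = 1
            G[3:6, 1] = 1
            merged = AnnotationMatrix(b.name, list(b.feature_ids), ["u", "v"], G)
        union = AnnotationMatrix(b.name, list(b.feature_ids), ["uv"],
                                 (merged.G[:, [0]] + merged.G[:, [1]]).clip(0, 1))
        sp = project_genesets(model, [merged], normalization="none")
        sp_u = project_genesets(model, [union], normalization="none")
        Y = compute_gss(model, sp).Y
        Yu = compute_gss(model, sp_u).Y
        np.testing.assert_allclose(Y[0] + Y[1], Yu[0], atol=1e-10)

    def test_empty_component_set_errors(self, rng):
        _, anns, _, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        with pytest.raises(ValueError, match="non-empty"):
            compute_gss(model, space, components=[])


class TestExcludeComponents:
    def test_dropping_nothing_is_identity(self, rng):
        _, anns, _, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        before = compute_gss(model, space).Y
        after = compute_gss(exclude_components(model, []), space).Y
        np.testing.assert_array_equal(before, after)

    def test_dropped_component_is_exactly_its_contribution(self, rng):
        _, anns, _, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        full = compute_gss(model, space)
        reduced = compute_gss(exclude_components(model, [0]), space)
        np.testing.assert_allclose(full.Y - reduced.Y, full.by_component[0],
                                   atol=1e-12)

    def test_dropping_everything_errors(self, rng):
        _, _, _, model = fitted_toy(rng)
        with pytest.raises(ValueError, match="all"):
            exclude_components(model, list(model.selected_components))

    def test_confounder_component_exclusion_flips_significance(self):
        """A set aligned with a strong confounder component loses its
        significance once that component is excluded from scoring."""
        rng = np.random.default_rng(7)
        p, n = 400, 24
        confounder = np.linspace(-1.5, 1.5, n)       # e.g. growth rate
        target = np.flatnonzero(rng.random(p) < 0.1)[:30]
        blocks = []
        for name in ("rna", "protein"):
            v = rng.normal(size=(p, n))
            v[target] += np.outer(np.full(len(target), 2.0), confounder)
            v -= v.mean(1, keepdims=True)
            blocks.append(OmicsBlock(name, [f"f{i}" for i in range(p)],
                                     [f"s{j}" for j in range(n)], v))
        G = np.zeros((p, 2), dtype=np.int8)
        G[target, 0] = 1                              # confounded set
        G[rng.choice(np.setdiff1d(np.arange(p), target), 30, replace=False),
          1] = 1                                      # background set
        anns = [AnnotationMatrix(b.name, list(b.feature_ids),
                                 ["cycle", "background"], G) for b in blocks]
        w = table_weights(blocks, "mfa")
        model = fit_mfa(blocks, w, n_components=5)
        space = project_genesets(model, anns)
        with_c = gss_significance(compute_gss(model, space), model, space)
        dropped = exclude_components(model, [0])
        space_d = project_genesets(dropped, anns)
        without_c = gss_significance(compute_gss(dropped, space_d), dropped,
                                     space_d)
        assert with_c.p[0].min() < 0.01
        assert without_c.p[0].min() > 0.05


class TestSignificance:
    def test_bh_adjustment_is_monotone_and_bounded(self, rng):
        _, anns, _, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        res = gss_significance(compute_gss(model, space), model, space)
        assert np.all(res.p_adj >= res.p - 1e-15)
        assert np.all(res.p_adj <= 1.0)
        # order preserved within each sample
        for j in range(res.p.shape[1]):
            order = np.argsort(res.p[:, j])
            assert np.all(np.diff(res.p_adj[order, j]) >= -1e-12)

    def test_analytic_null_matches_empirical_random_set_null(self, default_model):
        """Per-sample, the analytic membership null reproduces the moments
        of scores of size-matched random sets drawn from the data."""
        model, _ = default_model
        rng = np.random.default_rng(0)
        recon = {nm: model.reconstruct_block(nm) for nm in model.block_names}
        g, total, N = 50, 150, 1000
        draws = np.zeros((3000, len(model.sample_ids)))
        for nm in model.block_names:
            R = recon[nm]
            for b in range(draws.shape[0]):
                draws[b] += R[rng.choice(N, g, replace=False)].sum(0)
        draws /= total
        for j in (0, 10, 25):
            ana_mean = sum(g * recon[nm][:, j].mean()
                           for nm in model.block_names) / total
            ana_sd = np.sqrt(sum(g * recon[nm][:, j].var()
                                 * (N - g) / (N - 1)
                                 for nm in model.block_names)) / total
            assert draws[:, j].mean() == pytest.approx(ana_mean,
                                                       abs=4 * ana_sd / 54)
            assert draws[:, j].std() == pytest.approx(ana_sd, rel=0.08)

    def test_planted_strong_set_is_detected_in_affected_cluster(self):
        proj = simulate_project(SimulationConfig(seed=3, m_signal=0.8,
                                                 n_deg=25))
        centered = [preprocess_block(b) for b in proj.blocks]
        model = fit_mfa(centered, table_weights(centered, "mfa"),
                        n_components=5)
        space = project_genesets(model, proj.annotations)
        res = gss_significance(compute_gss(model, space), model, space)
        de = proj.truth.astype(bool)
        assert np.median(res.p[de]) < np.median(res.p[~de])
        # strongest DE (set, sample) pairs reach clear significance
        assert (res.p[de] < 0.05).mean() > 0.5

    def test_permutation_and_analytic_agree_on_toy(self, rng):
        _, anns, _, model = fitted_toy(rng, p=40, set_size=8)
        space = project_genesets(model, anns)
        res = compute_gss(model, space)
        ana = gss_significance(res, model, space, method="analytic")
        per = gss_significance(res, model, space, method="permutation",
                               n_draws=600, seed=1)
        # same ordering of evidence, similar scale
        mask = ana.p < 0.9
        assert np.corrcoef(ana.p[mask], per.p[mask])[0, 1] > 0.8

    def test_invalid_draws_errors(self, rng):
        _, anns, _, model = fitted_toy(rng)
        space = project_genesets(model, anns)
        res = compute_gss(model, space)
        with pytest.raises(ValueError, match="n_draws"):
            gss_significance(res, model, space, method="permutation",
                             n_draws=0)
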