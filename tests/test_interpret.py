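"""Cluster profiles, Wilcoxon DE, DE ranking, factor matching, RF importance."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import varimap
from varimap.containers import ValidationError
from varimap.factor import FactorModel
from varimap.interpret import ClusterProfile, _ranksum_vectorized


def norm_from(values, genes=None, cells=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return varimap.NormalizedMatrix(values, genes, cells)


class TestClusterProfiles:
    def test_single_cluster_equals_global_mean(self):
        norm = norm_from(np.arange(12).reshape(3, 4))
        prof = varimap.cluster_mean_profiles(norm, ["a"] * 4)
        assert np.allclose(prof.means["a"], norm.values.mean(axis=1))

    def test_disjoint_markers_zero_in_other_cluster(self):
        vals = np.array([[2.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 3.0]])
        prof = varimap.cluster_mean_profiles(norm_from(vals), ["a", "a", "b", "b"])
        assert prof.means.loc["g0", "b"] == 0.0
        assert prof.means.loc["g1", "a"] == 0.0

    def test_cell_order_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 20))
        labels = np.array(["a", "b"] * 10)
        prof1 = varimap.cluster_mean_profiles(norm_from(vals), labels)
        perm = rng.permutation(20)
        norm2 = varimap.NormalizedMatrix(
            vals[:, perm], prof1.means.index.tolist(), [f"c{i}" for i in perm]
        )
        prof2 = varimap.cluster_mean_profiles(norm2, labels[perm])
        pd.testing.assert_frame_equal(prof1.means, prof2.means)

    def test_unlabeled_cells_error(self):
        with pytest.raises(ValidationError, match="unlabeled"):
            varimap.cluster_mean_profiles(norm_from(np.ones((2, 3))), ["a", None, "a"])

    def test_small_cluster_flagged(self):
        prof = varimap.cluster_mean_profiles(
            norm_from(np.ones((2, 5))), ["a", "a", "a", "a", "b"]
        )
        assert prof.small_clusters == ["b"]


class TestDEWilcoxon:
    def test_exact_small_sample_p(self):
        norm = norm_from([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]])
        labels = ["in", "in", "in", "out", "out", "out"]
        de = varimap.de_wilcoxon(norm, labels, "in")
        assert de.loc[0, "p"] == pytest.approx(0.1)

    def test_identical_distributions_p_near_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (4, 2))  # same values in both groups
        norm = norm_from(vals)
        de = varimap.de_wilcoxon(norm, ["in"] * 4 + ["out"] * 4, "in")
        assert (de["p"] >= 0.9).all()

    def test_rank_invariance_under_scaling(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 30))
        labels = ["in"] * 12 + ["out"] * 18
        p1 = varimap.de_wilcoxon(norm_from(vals), labels, "in")["p"]
        p2 = varimap.de_wilcoxon(norm_from(vals * 2.0), labels, "in")["p"]
        assert np.allclose(p1, p2)

    def test_vectorized_matches_scipy(self):
        """The shared-rank normal approximation agrees with scipy per gene."""
        rng = np.random.default_rng(2)
        vals = np.round(rng.normal(size=(30, 40)), 1)  # induce ties
        in_mask = np.zeros(40, dtype=bool)
        in_mask[:15] = True
        ours = _ranksum_vectorized(vals, in_mask)
        ref = np.array(
            [
                scipy.stats.mannwhitneyu(
                    vals[g, in_mask], vals[g, ~in_mask], method="asymptotic"
                ).pvalue
                for g in range(30)
            ]
        )
        assert np.allclose(ours, ref, rtol=1e-10)

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(3)
        norm = norm_from(rng.normal(size=(20, 40)))
        de = varimap.de_wilcoxon(norm, ["in"] * 20 + ["out"] * 20, "in")
        assert (de["p_adj"] >= de["p"] - 1e-15).all()

    def test_cluster_covering_all_cells_error(self):
        with pytest.raises(ValidationError, match="out-group"):
            varimap.de_wilcoxon(norm_from(np.ones((2, 4))), ["in"] * 4, "in")


class TestRankDEGenes:
    @pytest.mark.parametrize(
        "p,logfc,score",
        [(1.0, 5.0, 0.0), (0.01, 1.0, 2.0), (0.5, 0.0, 0.0)],
    )
    def test_score_values(self, p, logfc, score):
        df = pd.DataFrame({"gene": ["g"], "p": [p], "logFC": [logfc]})
        out = varimap.rank_de_genes(df)
        assert out.loc[0, "score"] == pytest.approx(score)

    def test_ordering_decreasing(self):
        df = pd.DataFrame(
            {"gene": list("abc"), "p": [0.01, 1e-5, 0.5], "logFC": [1.0, 2.0, -3.0]}
        )
        out = varimap.rank_de_genes(df)
        assert list(out["gene"]) == ["b", "a", "c"]
        assert out.loc[2, "score"] < 0


def profile_with_top_de(means: pd.DataFrame, top_de):
    return ClusterProfile(
        means=means, sizes=pd.Series(10, index=means.columns), top_de=top_de
    )


def model_with_loadings(loadings, gene_ids):
    loadings = np.asarray(loadings, float)
    return FactorModel(
        loadings=loadings,
        scores=np.random.default_rng(0).normal(size=(20, loadings.shape[1])),
        rotation=np.eye(loadings.shape[1]),
        variance_explained=np.ones(loadings.shape[1]),
        gene_ids=gene_ids,
        cell_ids=[f"c{i}" for i in range(20)],
    )


class TestFactorClusterCorrelation:
    def test_exact_linear_relationships(self):
        genes = [f"g{i}" for i in range(5)]
        means = pd.DataFrame({"clu": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=genes)
        loadings = np.column_stack([[2, 4, 6, 8, 10], [5, 4, 3, 2, 1]]).astype(float)
        model = model_with_loadings(loadings, genes)
        prof = profile_with_top_de(means, {"clu": genes})
        match = varimap.factor_cluster_correlation(prof, model, top_n=5)
        assert match.correlation.loc["clu", "PC1"] == pytest.approx(1.0)
        assert match.correlation.loc["clu", "PC2"] == pytest.approx(-1.0)

    def test_loading_rescaling_invariant(self):
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        means = pd.DataFrame({"clu": rng.normal(size=6)}, index=genes)
        L = rng.normal(size=(6, 2))
        prof = profile_with_top_de(means, {"clu": genes})
        m1 = varimap.factor_cluster_correlation(prof, model_with_loadings(L, genes), top_n=6)
        m2 = varimap.factor_cluster_correlation(
            prof, model_with_loadings(L * 7.5, genes), top_n=6
        )
        pd.testing.assert_frame_equal(m1.correlation, m2.correlation)
        assert m1.correlation.abs().le(1.0 + 1e-12).all().all()

    def test_missing_genes_dropped_few_left_nan(self):
        genes = [f"g{i}" for i in range(4)]
        means = pd.DataFrame({"clu": [1.0, 2.0, 3.0, 4.0]}, index=genes)
        prof = profile_with_top_de(means, {"clu": ["g0", "g1", "nope1", "nope2"]})
        model = model_with_loadings(np.ones((4, 1)), genes)
        match = varimap.factor_cluster_correlation(prof, model, top_n=4)
        assert np.isnan(match.correlation.loc["clu", "PC1"])

    def test_top_n_below_three_rejected(self):
        genes = ["a", "b", "c"]
        prof = profile_with_top_de(
            pd.DataFrame({"clu": [1.0, 2.0, 3.0]}, index=genes), {"clu": genes}
        )
        with pytest.raises(ValidationError, match="top_n"):
            varimap.factor_cluster_correlation(
                prof, model_with_loadings(np.ones((3, 1)), genes), top_n=2
            )


def scores_model(scores):
    scores = np.asarray(scores, float)
    K = scores.shape[1]
    return FactorModel(
        loadings=np.random.default_rng(1).normal(size=(5, K)),
        scores=scores,
        rotation=np.eye(K),
        variance_explained=scores.var(axis=0, ddof=1),
        gene_ids=[f"g{i}" for i in range(5)],
        cell_ids=[f"c{i}" for i in range(scores.shape[0])],
    )


class TestCovariateImportance:
    def test_informative_factor_ranked_first(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(1000, 10))
        labels = np.where(scores[:, 3] > 0, "DA", "LEW")
        report = varimap.covariate_factor_importance(scores_model(scores), labels, seed=0)
        assert report.ranked_factors()[0] == "PC4"
        assert report.accuracy >= 0.99
        assert 0 <= report.sensitivity <= 1 and 0 <= report.specificity <= 1

    def test_null_labels_accuracy_in_binomial_band(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(1000, 10))
        labels = rng.choice(["DA", "LEW"], size=1000)
        report = varimap.covariate_factor_importance(scores_model(scores), labels, seed=0)
        n_test = 250
        majority = max(np.mean(labels == "DA"), np.mean(labels == "LEW"))
        band = 1.96 * np.sqrt(majority * (1 - majority) / n_test)
        assert abs(report.accuracy - majority) <= band + 0.05

    def test_duplicated_noise_factor_keeps_top(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(800, 6))
        labels = np.where(scores[:, 2] > 0, "DA", "LEW")
        base = varimap.covariate_factor_importance(scores_model(scores), labels, seed=1)
        dup = np.column_stack([scores, scores[:, 5]])
        extended = varimap.covariate_factor_importance(scores_model(dup), labels, seed=1)
        assert base.ranked_factors()[0] == extended.ranked_factors()[0] == "PC3"

    def test_importance_invariant_to_factor_order(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=(600, 5))
        labels = np.where(scores[:, 1] > 0, "DA", "LEW")
        r1 = varimap.covariate_factor_importance(scores_model(scores), labels, seed=2)
        perm = [4, 1, 0, 3, 2]
        r2 = varimap.covariate_factor_importance(scores_model(scores[:, perm]), labels, seed=2)
        # the informative factor (original column 1) stays on top
        assert r1.ranked_factors()[0] == "PC2"
        assert r2.ranked_factors()[0] == "PC2"  # column 1 is position 1 in perm too

    def test_single_class_rejected(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(50, 3))
        with pytest.raises(ValidationError, match="two covariate classes"):
            varimap.covariate_factor_importance(scores_model(scores), ["DA"] * 50)


class TestTechnicalScreen:
    def meta_for(self, model, lib):
        return pd.DataFrame(
            {
                "library_size": lib,
                "n_genes_expressed": np.random.default_rng(1).poisson(500, len(lib)),
                "mito_fraction": np.random.default_rng(2).beta(2, 18, len(lib)),
            },
            index=model.cell_ids,
        )

    def test_library_factor_flagged(self):
        rng = np.random.default_rng(10)
        lib = rng.gamma(5, 1000, 300)
        scores = np.column_stack([lib, rng.normal(size=300)])
        model = scores_model(scores)
        table = varimap.technical_covariate_check(model, self.meta_for(model, lib))
        assert table.loc["PC1", "library_size"] == pytest.approx(1.0)
        assert bool(table.loc["PC1", "technical_flag"])

    def test_threshold_one_flags_nothing(self):
        rng = np.random.default_rng(11)
        lib = rng.gamma(5, 1000, 300)
        scores = np.column_stack([lib, rng.normal(size=300)])
        model = scores_model(scores)
        table = varimap.technical_covariate_check(
            model, self.meta_for(model, lib), flag_threshold=1.0
        )
        assert not table["technical_flag"].any()

    def test_constant_covariate_zero(self):
        rng = np.random.default_rng(12)
        model = scores_model(rng.normal(size=(100, 2)))
        meta = self.meta_for(model, np.full(100, 2000.0))
        table = varimap.technical_covariate_check(model, meta)
        assert (table["library_size"] == 0).all()

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(13)
        model = scores_model(rng.normal(size=(2000, 5)))
        meta = self.meta_for(model, rng.gamma(5, 1000, 2000))
        table = varimap.technical_covariate_check(model, meta)
        assert table["max_abs_r"].max() < 0.1
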