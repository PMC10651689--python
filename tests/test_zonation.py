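"""Zonation axis detection, per-spot scores, layer and ortholog correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import varimap
from varimap.containers import ValidationError
from varimap.factor import FactorModel
from varimap.zonation import MarkerSets


@pytest.fixture(scope="module")
def lobule(spots_sim):
    """Filtered spots plus a fitted spatial PCA and marker sets from truth."""
    spots, truth = spots_sim["spots"], spots_sim["truth"]
    filtered, _ = varimap.spatial_gene_filter(spots)
    model = varimap.fit_spatial_pca(filtered, K=5)
    pp = [g for g, d in truth.zonated_gene_directions.items() if d == "periportal"]
    pc = [g for g, d in truth.zonated_gene_directions.items() if d == "pericentral"]
    markers = MarkerSets(pp[:10], pc[:10])
    return {
        "spots": filtered,
        "model": model,
        "markers": markers,
        "layers": truth.spot_layer_of_spot,
    }


class TestSpatialPCA:
    def test_gradient_dominates_pc1(self, lobule):
        ve = lobule["model"].variance_explained
        assert ve[0] > 2 * ve[1]

    def test_deterministic(self, lobule):
        refit = varimap.fit_spatial_pca(lobule["spots"], K=5)
        assert np.allclose(refit.loadings, lobule["model"].loadings)
        assert np.allclose(refit.scores, lobule["model"].scores)

    def test_shuffled_layers_uncorrelated(self, lobule):
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(lobule["layers"])
        r = np.corrcoef(lobule["model"].scores[:, 0], shuffled)[0, 1]
        assert abs(r) < 0.2


def toy_model(loadings, gene_ids):
    loadings = np.asarray(loadings, float)
    K = loadings.shape[1]
    return FactorModel(
        loadings=loadings,
        scores=np.random.default_rng(0).normal(size=(10, K)),
        rotation=np.eye(K),
        variance_explained=np.arange(K, 0, -1).astype(float),
        gene_ids=gene_ids,
        cell_ids=[f"s{i}" for i in range(10)],
    )


class TestIdentifyAxis:
    def constructed(self, pp_sign=1.0):
        rng = np.random.default_rng(1)
        genes = [f"pp{i}" for i in range(5)] + [f"cv{i}" for i in range(5)] + [
            f"bg{i}" for i in range(30)
        ]
        L = rng.normal(scale=0.05, size=(40, 3))
        L[:5, 1] = 0.9 * pp_sign
        L[5:10, 1] = -0.9 * pp_sign
        model = toy_model(L, genes)
        markers = MarkerSets([f"pp{i}" for i in range(5)], [f"cv{i}" for i in range(5)])
        return model, markers

    def test_selects_separating_factor_pp_positive(self):
        model, markers = self.constructed(+1.0)
        axis = varimap.identify_zonation_axis(model, markers)
        assert axis.factor == 1 and axis.sign == +1

    def test_sign_flipped_when_pp_negative(self):
        model, markers = self.constructed(-1.0)
        axis = varimap.identify_zonation_axis(model, markers)
        assert axis.factor == 1 and axis.sign == -1

    def test_invariant_to_model_sign_flip(self):
        model, markers = self.constructed(+1.0)
        flipped = FactorModel(
            loadings=-model.loadings,
            scores=-model.scores,
            rotation=model.rotation,
            variance_explained=model.variance_explained,
            gene_ids=model.gene_ids,
            cell_ids=model.cell_ids,
        )
        a1 = varimap.identify_zonation_axis(model, markers)
        a2 = varimap.identify_zonation_axis(flipped, markers)
        assert a1.factor == a2.factor
        # in both cases the reported axis is periportal-positive
        assert a1.sign * 1 == +1 and a2.sign * -1 == +1

    def test_no_separation_errors(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        model = toy_model(rng.normal(scale=0.1, size=(40, 3)), genes)
        markers = MarkerSets(genes[:5], genes[5:10])
        with pytest.raises(ValidationError, match="marker"):
            varimap.identify_zonation_axis(model, markers, alpha=1e-6)

    def test_too_few_markers_rejected(self, lobule):
        with pytest.raises(ValidationError, match=">= 3 markers"):
            varimap.identify_zonation_axis(
                lobule["model"], MarkerSets(["absent1", "absent2", "absent3"], ["x", "y", "z"])
            )


class TestZonationScore:
    def test_standardized_and_sign_convention(self, lobule):
        axis = varimap.identify_zonation_axis(lobule["model"], lobule["markers"])
        score = varimap.zonation_score(lobule["spots"], axis, lobule["model"])
        assert abs(score.mean()) < 1e-9
        assert abs(score.std(ddof=0) - 1.0) < 1e-9
        import dataclasses

        flipped = dataclasses.replace(axis, sign=-axis.sign)
        neg = varimap.zonation_score(lobule["spots"], flipped, lobule["model"])
        assert np.allclose(score.to_numpy(), -neg.to_numpy())

    def test_monotone_with_layer(self, lobule):
        axis = varimap.identify_zonation_axis(lobule["model"], lobule["markers"])
        score = varimap.zonation_score(lobule["spots"], axis, lobule["model"])
        rho = scipy.stats.spearmanr(lobule["layers"], score.to_numpy()).statistic
        assert abs(rho) > 0.9


class TestLayerClusterCorrelation:
    def test_identical_profiles_diagonal_one(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        prof = pd.DataFrame(rng.normal(size=(20, 4)), index=genes, columns=list("abcd"))
        r, stars = varimap.layer_cluster_correlation(prof, prof.copy(), genes)
        assert np.allclose(np.diag(r.to_numpy().astype(float)), 1.0)

    def test_opposing_gradients_anticorrelated(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(10)]
        a = pd.DataFrame(rng.normal(size=(10, 3)), index=genes, columns=["c1", "c2", "c3"])
        b = pd.DataFrame(-a.to_numpy(), index=genes, columns=["l1", "l2", "l3"])
        r, _ = varimap.layer_cluster_correlation(a, b, genes)
        # a layer profile that opposes a cluster's gradient correlates at -1
        assert r.loc["c1", "l1"] == pytest.approx(-1.0)
        assert r.loc["c2", "l2"] == pytest.approx(-1.0)

    def test_affine_invariance_per_side(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(15)]
        a = pd.DataFrame(rng.normal(size=(15, 3)), index=genes, columns=list("abc"))
        b = pd.DataFrame(rng.normal(size=(15, 4)), index=genes, columns=list("wxyz"))
        r1, _ = varimap.layer_cluster_correlation(a, b, genes)
        scale = pd.Series(rng.gamma(2, 1, 15) + 0.1, index=genes)
        shift = pd.Series(rng.normal(size=15), index=genes)
        a2 = a.mul(scale, axis=0).add(shift, axis=0)
        r2, _ = varimap.layer_cluster_correlation(a2, b, genes)
        assert np.allclose(r1.to_numpy().astype(float), r2.to_numpy().astype(float))

    def test_too_few_shared_genes(self):
        a = pd.DataFrame({"x": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError, match="shared genes"):
            varimap.layer_cluster_correlation(a, a.copy(), ["g1", "g2"])

    def test_periportal_cluster_monotone_over_layers(self, spots_sim):
        """A periportal-like profile correlates increasingly with higher layers."""
        spots, truth = spots_sim["spots"], spots_sim["truth"]
        X = spots.counts.X.toarray().astype(float)
        layers = truth.spot_layer_of_spot
        uniq = np.unique(layers)
        layer_means = pd.DataFrame(
            {f"L{l}": X[:, layers == l].mean(axis=1) for l in uniq},
            index=spots.counts.gene_ids,
        )
        zonated = list(truth.zonated_gene_directions)
        clusters = pd.DataFrame(
            {
                "pp_like": layer_means[f"L{uniq.max()}"],
                "pc_like": layer_means[f"L{uniq.min()}"],
            }
        )
        r, _ = varimap.layer_cluster_correlation(clusters, layer_means, zonated)
        vals = r.loc["pp_like"].to_numpy(float)
        # rises from strongly negative at the pericentral end to strongly
        # positive at the periportal end, monotone up to sampling jitter
        rho = scipy.stats.spearmanr(np.arange(len(vals)), vals).statistic
        assert rho > 0.95
        assert vals[0] < -0.9 and vals[-1] > 0.9


class TestOrthologCorrelation:
    def profiles_from(self, seed, prefix=""):
        cfg = varimap.default_config(seed=seed, n_cells_per_sample=150, n_genes=500)
        counts, meta, _ = varimap.simulate_cells(cfg)
        norm = varimap.normalize_log(counts)
        prof = varimap.cluster_mean_profiles(norm, meta["cluster"])
        means = prof.means
        if prefix:
            means = means.rename(index=lambda g: prefix + g)
        return means

    def test_identity_map_diagonal(self):
        a = self.profiles_from(0)
        om = pd.DataFrame({"a": a.index, "b": a.index})
        r, rows, cols = varimap.ortholog_cluster_correlation(a, a.copy(), om, hvg_n=400)
        for cl in a.columns:
            assert r.loc[cl, cl] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_renamed_species_match(self, seed):
        """Two independent atlases sharing cell-type programs under renamed
        genes: each cluster's best correlate is its own type."""
        a = self.profiles_from(seed * 2 + 1)
        b = self.profiles_from(seed * 2 + 2, prefix="sp2_")
        om = pd.DataFrame({"a": a.index, "b": "sp2_" + a.index})
        r, _, _ = varimap.ortholog_cluster_correlation(a, b, om, hvg_n=400)
        for cl in a.columns:
            assert r.loc[cl].idxmax() == cl

    def test_empty_map_rejected(self):
        a = self.profiles_from(3)
        with pytest.raises(ValidationError, match="empty"):
            varimap.ortholog_cluster_correlation(a, a, pd.DataFrame(columns=["a", "b"]))

    def test_duplicated_pairs_dropped(self):
        a = self.profiles_from(5)
        genes = list(a.index[:50])
        om = pd.DataFrame({"a": genes + [genes[0]], "b": genes + ["other"]})
        r, _, _ = varimap.ortholog_cluster_correlation(a, a.copy(), om, hvg_n=500)
        assert r.shape == (4, 4)
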