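"""Shared fixtures: one mid-sized synthetic atlas analyzed once per session."""

import numpy as np
import pytest

import varimap


@pytest.fixture(scope="session")
def atlas():
    """Simulated two-strain atlas at reduced scale (4 x 500 cells, 900 genes)."""
    cfg = varimap.default_config(seed=7, n_cells_per_sample=500, n_genes=900)
    counts, meta, truth = varimap.simulate_cells(cfg)
    return {"config": cfg, "counts": counts, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def analysis(atlas):
    """Full factor analysis of the session atlas: norm, HVGs, varimax model."""
    counts, meta = atlas["counts"], atlas["meta"]
    norm = varimap.normalize_log(counts)
    hvgs = varimap.select_hvgs(norm, 700)
    norm_h = norm.subset_genes(hvgs)
    scaled = varimap.scale_genes(norm_h)
    model = varimap.varimax_rotate(varimap.fit_pca(scaled, 25))
    profiles = varimap.cluster_mean_profiles(norm_h, meta["cluster"])
    for cl in profiles.means.columns:
        de = varimap.de_wilcoxon(norm_h, meta["cluster"], cl)
        profiles.top_de[cl] = list(varimap.rank_de_genes(de)["gene"])
    return {
        "norm": norm,
        "norm_h": norm_h,
        "scaled": scaled,
        "model": model,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def spots_sim():
    cfg = varimap.default_config(seed=7, n_cells_per_sample=200, n_genes=600)
    spots, truth = varimap.simulate_spots(cfg)
    return {"spots": spots, "truth": truth, "config": cfg}


def strain_factor_indices(model, meta):
    """(global, restricted) strain factor indices by standardized mean difference."""
    strains = meta["strain"].to_numpy()
    mye = (meta["cluster"] == "Myeloid").to_numpy()

    def smd(sv, lab):
        a, b = sv[lab == "DA"], sv[lab == "LEW"]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        return abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0

    K = model.n_factors
    g = np.array([smd(model.scores[:, k], strains) for k in range(K)])
    gf = int(g.argmax())
    excess = np.array(
        [smd(model.scores[mye][:, k], strains[mye]) - g[k] for k in range(K)]
    )
    excess[gf] = -np.inf
    return gf, int(excess.argmax())
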