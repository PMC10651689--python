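# varimap

Varimax-rotated PCA for deconvolving covariate signals from cell-type
signals in single-cell expression data.

## The problem

In multi-sample single-cell RNA-seq studies, the variation of interest —
for example, differences between two inbred rat strains in a liver cell
atlas — is entangled with cell-type identity programs, per-sample batch
effects, and technical artifacts such as ambient RNA leaked from fragile
hepatocytes into every droplet. Standard PCA spreads these sources
across components; clustering absorbs them into cell-type labels.

`varimap` separates them with an interpretable matrix factorization.
The scaled expression matrix **X** (genes × cells) is decomposed as

```
X ≈ L Sᵀ,   L: genes × K loadings,   S: cells × K scores
```

and the PCA basis is rotated by an orthogonal **R** chosen to maximize
the varimax criterion — the variance of squared loadings within each
factor, `Σₖ Var₉(L²₉ₖ)` — which concentrates each factor on few genes
("simple structure") while leaving the reconstruction `S Lᵀ` unchanged.
Factors are then interpreted automatically:

* **cluster matching** — Pearson correlation between each cluster's
  mean expression and each factor's loadings over the cluster's top
  differentially expressed genes (Wilcoxon rank-sum, ranked by
  `−log₁₀(p)·logFC`);
* **covariate association** — a random forest predicts the covariate
  (strain) from factor scores; mean decrease in Gini impurity ranks the
  factors carrying covariate signal;
* **technical screen** — correlation of scores with library size,
  expressed-gene count and mitochondrial fraction flags quality factors;
* **signatures** — each covariate factor's top-10 positively and
  negatively loaded genes become a portable signature, scored per cell
  on independent datasets with a rank-based (Mann–Whitney-U) statistic
  in [0, 1] that is invariant to monotone transforms of expression;
* **zonation** — for spatial data, a marker-anchored PCA axis detects
  the periportal–pericentral lobule gradient and scores each spot.

A negative-binomial synthetic-atlas generator with planted ground truth
(cell types, strain programs, ambient contamination, batch depths,
mitochondrial content, a 1-D zonation gradient) backs every stage with
parameter-recovery tests.

## Worked example

```python
import varimap

run = varimap.run_pipeline(
    {"seed": 42,
     "simulate": {"n_cells_per_sample": 500, "n_genes": 900},
     "hvg_n": 700, "K_varimax": 25},
    outdir="demo_run",
)
s = run.summary
print("cells after QC:      ", s["n_cells_after_qc"])
print("top Gini factors:    ", s["top_importance_factors"])
print("RF accuracy:         ", round(s["rf_accuracy"], 4))
print("global strain factor:", s["global_strain_factor"])
print("restricted factor:   ", s["restricted_strain_factor"],
      "->", s["restricted_factor_localized_to"])
print("zonation spearman:   ", round(s["zonation"]["spearman_vs_layer"], 3))
```

prints

```
cells after QC:       1996
top Gini factors:     ['varimax4', 'varimax5']
RF accuracy:          0.998
global strain factor: varimax4
restricted factor:    varimax5 -> Myeloid
zonation spearman:    0.982
```

Reading: of 2,000 simulated cells, 1,996 pass per-sample QC. Among 25
varimax factors the random forest ranks `varimax4` and `varimax5` as the
most strain-informative (held-out accuracy 99.8%). `varimax4` separates
the strains in every cell — the ambient-RNA-driven global strain factor —
while `varimax5` separates them only within myeloid cells, and the
cluster-correlation screen localizes it to the Myeloid cluster, matching
the planted ground truth. On the spatial arm, the marker-anchored PCA
axis tracks the true lobule layer with Spearman ρ = 0.98.

The same stages are available from the shell
(`varimap run --config cfg.json --outdir out --seed 1`, with
`simulate`/`qc`/`factorize`/`interpret`/`score`/`zonate` subcommands) and
as library functions (`fit_pca`, `varimax_rotate`, `extract_signature`,
`rank_signature_score`, `identify_zonation_axis`, ...) for real 10x-style
MTX inputs with per-sample QC thresholds in the config.

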