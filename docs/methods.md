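# Methods

## Factor model

The pipeline operates on a genes × cells matrix of log-normalized
(`log(1 + s·c/ℓ)`, scale `s` = 10,000, library size `ℓ`), gene-centered
and unit-variance-scaled expression restricted to highly variable genes
(top 2,000 by cross-cell variance of normalized expression by default;
clipping at ±10 after scaling). PCA is computed by symmetric
eigendecomposition of the smaller Gram matrix (genes × genes or
cells × cells, whichever is smaller), which is deterministic — no
randomized SVD — and exact for the K ≤ 30 factors used here. Scores are
the cell projections; `variance_explained[k]` equals the sample
variance (ddof = 1) of factor k's scores.

Varimax rotation maximizes `Σₖ Var₉(L²₉ₖ)` with the population-variance
convention (divisor = number of genes) — the oracle tests use the same
convention. The optimizer is the classical cyclic-pairwise scheme: for
each factor pair the optimal planar angle has the closed form
`4θ* = atan2(2Σuv − 2ΣuΣv/G, Σ(u²−v²) − ((Σu)²−(Σv)²)/G)` with
`u = x²−y², v = 2xy`; sweeps repeat until the criterion gain drops
below `tol` (default 1e-7, max 1000 sweeps; non-convergence returns the
result with `converged = False` and a warning). Kaiser row
normalization (rows of L scaled to unit length while optimizing,
restored after) is on by default, the standard practice; because the
restoration is a left-diagonal action, the applied rotation is still
exactly `L @ R` with orthogonal R, so scores rotate by the same R and
the reconstruction `S Lᵀ` is invariant to machine precision. After
rotation, factors are reordered by decreasing score variance and signed
so that each factor's largest-|loading| gene loads positively
(deterministic orientation; idempotent).

For K = 2 the pairwise angle formula is globally optimal, which the
test suite verifies against a 1e-5-grid search over θ ∈ [0, π/2) on
random loading matrices.

## Factor interpretation

*Cluster matching.* Cluster mean profiles use arithmetic means of
log-normalized expression. Differential expression is a per-gene
two-sided Wilcoxon rank-sum test of one cluster against the rest with
no fold-change or detection pre-filtering: exact enumeration when both
groups have ≤ 10 cells and no ties, otherwise a tie-corrected normal
approximation with continuity correction, computed from one shared rank
matrix (verified against `scipy.stats.mannwhitneyu` per gene). Fold
change is `ln((mean_in + ε)/(mean_out + ε))` with ε = 1e-9;
Benjamini–Hochberg adjusts across genes; genes are ranked by
`−log₁₀(p)·logFC` with p floored at 1e-300. The cluster–factor match is
the Pearson correlation between a cluster's mean profile and each
factor's loadings over that cluster's top-n DE genes, repeated for
n ∈ {10, 20, 30, 50}. Summary localization uses the n = 50 window: in
the synthetic atlas the very top of a cluster's DE list can consist
entirely of planted program genes with nearly equal means, which gives
the correlation no spread to work with; by n = 50 the list mixes
markers and program genes and the assignment is stable.

*Covariate association.* A 500-tree random forest (√K features per
split, impurity importance, fixed seed) is trained on a stratified
3:1 train/test split of factor scores against covariate labels.
Reported: per-factor mean decrease in Gini impurity, held-out accuracy,
and sensitivity/specificity with the first class in sorted label order
as positive. Tree count and depth are ecosystem defaults; only the
split ratio and the importance metric are fixed by the method.

*Two-factor structure.* Among all factors, the **global** covariate
factor maximizes the absolute standardized mean difference (SMD)
between covariate groups over all cells; the **restricted** factor
maximizes the excess of its within-cluster |SMD| over its global |SMD|
(excluding the global factor). The restricted factor's cluster
localization is then read off the cluster-correlation screen.

*Technical screen.* Pearson r of each factor's scores against library
size, expressed-gene count and mitochondrial fraction; factors with
max |r| above 0.5 are flagged. Constant covariates report r = 0 with a
note.

## Signatures

A factor's signature is its top-10 positively and top-10 negatively
loaded genes. Per-cell scoring ranks all genes within a cell by
decreasing expression with average ties, caps ranks above `r_max`
(default 1500) at `r_max + 1`, and computes
`1 − U′/(n_s·r_max)` with `U′ = Σranks − n_s(n_s+1)/2`, clamped to
[0, 1] — a Mann–Whitney-U statistic against the rest of the
transcriptome, invariant under any strictly increasing per-cell
transform, hence portable across normalizations and platforms. Ties
include genes with zero counts, which share the tied bottom ranks. The
bipolar score `(score₊ − score₋ + 1)/2` combines the two poles of a
directional factor; both pole scores are also available separately.
Group comparisons report the two-sided rank-sum p, the rank-biserial
effect size `2U/(n₁n₂) − 1`, and group medians, optionally restricted
to one cluster.

## Spatial zonation

Spatial spots pass a capture filter (a gene is removed when its
detection frequency is below 0.05 AND its maximum count is below 3;
an OR mode is available by config), then the same
log-normalize/scale/PCA chain runs with spots as observations. Among
the first five components, the zonation axis is the factor maximizing
the difference in mean loading rank between periportal and pericentral
marker genes, signed so periportal markers load positively; per-pole
enrichment is a one-sided rank-sum test of marker loadings against all
other genes, and an axis is only accepted if at least one pole is
significant at α = 0.05. Per-spot zonation scores are the standardized
signed factor scores (mean 0, sd 1, periportal-positive).

Cluster-vs-layer correlation z-scores each gene across each side's own
columns before computing Pearson r over shared genes (making the result
invariant to per-gene affine transforms on either side), with two-sided
t-approximation significance stars at 0.05/0.01/0.001. Cross-species
cluster correlation restricts to one-to-one orthologs within the
intersection of each side's top-2,000 most variable genes and orders
the heatmap by Ward linkage on 1 − r; fewer than 20 shared genes is an
error.

## Synthetic atlas: what it emulates

The generator draws negative-binomial counts (gamma–Poisson, shared
dispersion θ = 2) with per-cell mean `depth × rate`. Rates are built
from cell-type programs (30 marker genes per type at 12× background
weight; hepatocytes 60%, endothelial 15%, myeloid 15%, lymphocytes 10%),
strain programs, ambient contamination, and a mitochondrial component;
each (type × strain) rate vector is renormalized to unit mass, because
sequencing is compositional — a strain program shifts transcriptome
proportions, not a cell's total output. Depth is
`5,000 × batch multiplier × Gamma(12, 1/12)` (CV ≈ 0.29); the four
default samples (DA-1/DA-2/LEW-1/LEW-2, 1,000 cells each) carry depth
multipliers 1.0/1.2/0.9/1.1, so sample and strain are partially
confounded, as in real multi-sample designs. Mitochondrial fractions
are Beta-distributed per cell (mean 0.10) on genes prefixed `Mt-`,
matched by the QC module's default pattern.

Two strain effects are planted. A *hepatocyte* program — bipolar,
15 genes up in each strain at |log-FC| = 2 — becomes a **global**
strain signal because every droplet contains 25% ambient RNA from the
dominant, fragile hepatocytes (the ambient mix is a convex combination
of expected proportions before sampling, keeping the count law NB and
the planted effect linear in the rate). A *myeloid* program — unipolar,
20 genes up in one strain at log-FC = 2, baseline weight 2 — is
**restricted**: visible only within the 15% myeloid fraction. Effect
sizes were fixed once, during design, to reproduce the qualitative
structure such data show in practice (near-complete strain separation
on the leading covariate factor, random-forest accuracy ≈ 0.999) and
are exposed in the config. The depth distribution was likewise fixed at
design time: at substantially shallower depth, count-shrinkage noise
couples factor-score magnitude to library size for any factor whose
mean differs between cell types, which real deeply sequenced data do
not show at this strength.

The spatial arm places spots on a grid whose x-coordinate bins into
nine layers; 30 periportal-direction genes rise and 30
pericentral-direction genes fall log-linearly across layers over a
2-natural-log range at 3× background weight, 50 spots per layer.

What the generator does **not** emulate: doublets, empty droplets,
cell-cycle structure, within-type continuous heterogeneity beyond the
planted programs, realistic gene–gene correlation beyond the program
block structure, per-gene dispersion variation, or spatial structure in
the y-direction. Passing recovery tests therefore show that the
pipeline identifies planted covariate and gradient structure under
realistic count noise, compositional coupling, ambient contamination
and batch-depth confounding — not that it is robust to every artifact
of real tissue data.

## Numerical choices and degenerate inputs

- Sample standard deviation (ddof = 1) throughout scaling; constant
  genes scale to all zeros; z-scoring drops constant rows with a
  warning.
- QC boundaries: a cell exactly at the library-size minimum or the
  mitochondrial maximum is retained (thresholds are exclusive removal
  bounds); mito fraction of an empty cell is 0.
- HVG ties break by gene order (stable sort); duplicate gene symbols
  read from 10x features files get ".1", ".2", … suffixes in file
  order.
- K = 1 varimax returns the identity rotation; re-rotation of an
  already-rotated model is allowed and composes rotations.
- Signature scoring over partially absent gene lists warns and scores
  the present genes; an entirely absent list is an error, as is
  `r_max` ≤ the number of scored genes.
- The pipeline seed feeds every random draw (simulation, forest, split);
  two runs with the same config produce byte-identical artifacts, which
  the manifest's sha256 hashes make checkable.

## Problem sizes

Recovery studies run at 4 samples × 1,000 cells × 1,200 genes with
1,000 HVGs and K = 30 — large enough that planted-factor recovery,
localization, technical screens and signature transfer are stable
across seeds, and small enough that a twenty-seed study completes in a
few minutes on one CPU. The spatial arm uses 9 × 50 spots × 600 genes.

## Known limitations

- Oblique rotations (promax), sparse PCA and probabilistic factor
  models are out of scope; factors are orthogonal by construction even
  when the underlying biology is correlated.
- Cluster labels are inputs; no clustering is performed.
- The restricted-factor definition assumes exactly one globally
  dominant covariate factor; with several near-equal global factors the
  global/restricted split can be ambiguous.
- The DE module's normal approximation is accurate for group sizes
  ≳ 10; between the exact-path cutoff and that regime, p-values carry
  the usual continuity-correction conservatism.
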