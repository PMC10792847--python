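# Methods

This note documents the models, algorithms and numerical conventions
implemented in `omiclink`, the design choices made where several
conventions coexist in the field, and what the simulation-based tests do
and do not demonstrate.

## Data model

The unit of analysis is a gene. A matrix holds n genes × p omics
variables; each variable is described by its omic type (expression or
methylation), gene feature (promoter / gene body), cytosine context
(CG / CHG / CHH) and population. Missing cells are NaN. Splitting by
variable *kind* yields seven blocks — expression plus the six
feature × context methylation combinations — each containing all
populations' columns of that kind. Expression inputs are assumed to be
TPM-derived normalized counts, methylation inputs per-feature
read-by-density values; after the log2(1+x) transform both are treated
as unitless.

## Preprocessing

* **Presence filter**: keep genes with ≥1 non-missing expression *and*
  ≥1 non-missing methylation value.
* **Missing-fraction filter**: keep genes whose fraction of missing
  cells is ≤ a threshold (default 0.10). The threshold is applied *per
  gene* — the fraction of that gene's cells — because the filters
  operate on genes and a per-gene reading is what produces a gene count.
  With threshold 0 this is the complete-case filter. Filters compose in
  the order presence → missing-fraction, and the pipeline logs the count
  after each stage.
* **Log transform**: x ↦ log2(1+x) with configurable pseudo-count and
  base. The pseudo-count of 1 reflects the convention that genes with
  TPM ≤ 1 are considered unexpressed, so zeros map to zero. The
  transform is applied uniformly to expression and methylation columns.
* **Centering/scaling**: per-column z-scores using the sample (n−1)
  standard deviation, the convention of the R ecosystem this workflow
  interoperates with. Statistics use non-missing cells only;
  zero-variance columns are an error, not silently dropped.
* **Clamping**: values clipped into [−2, 2] (display and heatmap
  convention; idempotent).

## Exploratory statistics

**Spearman correlation** between variable pairs uses pairwise-complete
observations with average ranks for ties (equivalently, Pearson
correlation of mid-ranks on the shared rows). Pairs with fewer than 3
complete rows are rejected. Variables are arranged by the **angular
order of the eigenvectors (AOE)**: each variable is projected onto the
plane of the correlation matrix's two leading eigenvectors, assigned the
angle atan2(e₂ᵢ, e₁ᵢ) mapped into [0, 2π), and sorted ascending with
ties broken by input index. The circular order is anchored at the
smallest angle; any anchor gives the same cyclic arrangement. A
correlation matrix with no off-diagonal structure keeps the input order
(the leading eigen-pair is then degenerate and any angular order would
be arbitrary).

**PCA with missing values** uses NIPALS: per component, alternating
least-squares updates of scores and loadings in which every inner sum
skips missing cells, iterated until the relative change of the score
vector falls below 1e−6 (at most 500 iterations; non-convergence is an
error carrying the achieved tolerance). Deflation subtracts the rank-one
reconstruction at observed cells. Explained variance per component is
the reduction of the observed-cell residual sum of squares relative to
the total. On complete data the result equals SVD-based PCA up to sign;
the sign is fixed so each component's largest-|loading| entry is
positive.

## Design-weighted multi-block PLS

Blocks must be complete, centered and scaled. For each component:

1. initialize a_j as block j's leading right singular vector
   (deterministic — no random starts);
2. iterate: inner target ω_j = Σ_k c_jk s_jk t_k with t_k = X_k a_k,
   then a_j ← X_jᵀ ω_j / ‖X_jᵀ ω_j‖, where s_jk is 1 (horst scheme,
   default), sign(cov) (centroid) or cov (factorial); stop when the
   largest loading change (up to sign) is below tol = 1e−6 or after
   max_iter = 100 inner iterations — non-convergence is recorded on the
   model and warned about, not fatal, since the loadings are stable to
   ~1e−4 by then;
3. set t_j = X_j a_j and deflate every block on its own variate:
   X_j ← X_j − t_j (t_jᵀ X_j)/(t_jᵀ t_j).

Own-variate deflation makes each block's variates mutually orthogonal,
which the tests assert numerically, and is the operative convention for
everything downstream. The alternative regression-mode convention of the
mixOmics reference — predictor blocks deflated on their own variate, the
response block deflated by the *average* projection onto the other
blocks' variates — is available through
`BlockPlsConfig(mode="regression", response_block=...)`. Both routes are
cross-checked against mixOmics `block.pls` (canonical and regression
modes) in the test suite; agreement is ~1e−5 on loadings, limited only
by the iteration tolerances. An isolated block (all design weights zero)
has no inner target and is rejected by name. Signs follow the same
largest-|loading|-positive rule as the PCA.

The default design for methylome-on-transcriptome integration weights
every methylation–expression pair 1, methylation–methylation pairs 0.1,
and the diagonal 0, focusing the latent components on the
methylation/expression interplay while retaining weak links among
methylation contexts. Two components per block are the default.

## Denoising and the clustered image map

Denoising projects each block onto the span of its variates:
X̂_j = T_j (T_jᵀT_j)⁻¹ T_jᵀ X_j, residual R_j = X_j − X̂_j. Least-squares
projection is used rather than an explicit components × loadings product
because it is the unique reconstruction with X = X̂ + R and R ⟂ span(T);
under own-variate deflation the two coincide. The decomposition is exact
to machine precision, rank(X̂_j) ≤ H, and projecting twice changes
nothing — all asserted in tests. A rank-deficient variate Gram matrix is
an error.

The clustered image map applies, in fixed order, the three optional
transforms — `denoise`, `scale2` (center and scale each column a second
time), `cutoff` (clamp to [−2, 2]) — then concatenates the blocks and
clusters rows and columns hierarchically with **Euclidean distance and
Ward linkage** (the squared-Euclidean "ward.D2" convention of
scipy/modern R). The gene tree is cut into the smallest-height partition
with exactly k groups (default k = 4), labels assigned by first
appearance in leaf order; group × variable mean profiles summarize each
typology. The heatmap color scale is pinned to [−2, 2]. The Ward
implementation is verified against a brute-force Lance–Williams
agglomeration oracle on small instances (identical merge sequences and
heights).

## Candidate selection and MA comparison

A master-driver candidate has **every** methylation z-score > 1 and
**every** expression z-score < −1 (strict inequalities, as the
thresholds are conventionally quoted). The rule quantifies over all
cells and is therefore only defined on a complete matrix; the complete
case set is used. Thresholds are applied to the re-standardized
(`scale2`) output *before* clamping — observationally equivalent, since
clamping at ±2 cannot change a ±1 comparison. Venn comparison of the
non-denoised and denoised candidate sets reports disjoint only-a /
shared / only-b lists satisfying inclusion–exclusion exactly. The MA
table records, per cell, M = denoised − non-denoised and
A = (denoised + non-denoised)/2 on the log2-derived scale, flagging
|M| > 1; denoised is the minuend because the comparison quantifies the
changes denoising introduces.

## Synthetic data generator

The generator emulates the structure of a 10-population poplar-style
matrix, not its exact marginals. Values are drawn directly on the
log2-like scale:

value(gene i, kind k, population q) = μ_ik + gᵢ + c_ik + ε_ikq, truncated
at 0,

with μ_ik = baseline (3.0) + typology offset, gᵢ ~ N(0, 0.2²) a shared
gene effect, c_ik the gene × kind component shared by all populations,
and ε_ikq per-population noise. The noise budget is
var(c) + var(ε) = noise_sd² with the shared fraction equal to
`population_correlation` (default 0.9), which reproduces the near-unit
inter-population Spearman correlations of population-aggregated data.
The four typology templates encode, in units of the between-gene spread:
(1) high expression / low methylation everywhere; (2) low expression,
low CG gene-body methylation, moderate elsewhere; (3) high methylation,
moderately low expression; (4) high expression and CG gene-body
methylation, moderate elsewhere. Drivers (default 30) overwrite the
template with +2.5 on all methylation kinds and −2.5 on expression.

Distributional features: the shared component of the three promoter
kinds is a scaled Student-t (df 3), so a few genes carry extreme
promoter methylation consistently across populations — the feature that
survives log transformation in real promoter data; expression cells
below 1 (the "unexpressed" boundary) collapse to exactly 0 with
probability 0.3, creating the expressed/unexpressed bimodality.
Missingness (5% of cells overall) is concentrated in a random 35% of
non-driver genes rather than spread uniformly: real missingness is
gene-structured (most genes complete, a minority carrying most holes),
and uniform per-cell missingness at 5% would leave almost no complete
cases (0.95⁷⁰ ≈ 2.7%), making the complete-case integration stage
meaningless. Drivers stay complete so the all-populations selection rule
is well defined on the truth. Fixed config (including seed) gives
bit-identical output.

Free parameters not dictated by the emulated study design —
noise_sd = 0.4 and gene_effect_sd = 0.2, against a between-gene template
spread of 1 — were chosen once as the regime of population-aggregated
data (each population value averages many genotypes, so residual
inter-population noise is well below the between-gene spread) and are
the conditions under which the planted-signal recovery guarantees below
hold.

## What the simulations show — and don't

Under generator defaults, the end-to-end workflow (filters → block PLS →
denoise → rescale → extreme-profile selection) recovers the planted
drivers with mean sensitivity ≳ 0.95 and essentially zero false
discovery, and the k=4 Ward cut recovers the planted typologies with
ARI ≳ 0.94 (10 seeds; the acceptance tests assert ≥ 0.9 / ≤ 0.1 / ≥ 0.9).
Under a high-idiosyncratic-noise configuration (noise_sd 1.0,
population correlation 0.5) the denoised candidate set contains the
non-denoised one in ≥ 8/10 seeds and is strictly larger — the
qualitative signature that denoising adds sensitivity without losing
candidates. These are statements about the generator's Gaussian-plus-t,
linear, block-structured world: real methylome data add batch structure,
context-specific dependence between features, and non-linear
methylation–expression coupling that the generator does not model, so
passing tests certify the correctness and calibration of the machinery,
not biological performance on any particular dataset.

## Numerical conventions and degenerate inputs

* Tolerances: block-PLS inner loop 1e−6 (∞-norm on loadings, sign-aware),
  NIPALS 1e−6 relative score change; oracle-equivalence tests tighten
  these where they assert 1e−6-level agreement.
* All sign indeterminacies resolved by making the largest-|loading|
  entry positive (ties → lowest index).
* Deterministic initializations throughout (leading singular vectors;
  max-variance column for NIPALS); the only randomness in the package is
  the generator's seeded RNG.
* Degenerate inputs that raise by design: duplicate gene IDs,
  all-missing columns, zero-variance columns at scaling, constant
  columns, variable pairs with <3 complete rows, isolated blocks,
  missing values where an operation requires completeness, k larger
  than the gene count.
* Problem sizes in the shipped tests and reproduction script (2000-gene
  simulations, 10 seeds, 8-row clustering oracles, 20 two-block
  instances) were chosen to exercise every code path at desk scale;
  the library itself is vectorized and handles matrices with tens of
  thousands of genes.

## Known limitations

* No imputation: missing values are handled by deletion, and the
  integration stage requires complete cases.
* No batch-effect correction, no sparse (penalized) variable selection,
  no discriminant variants, no cross-validation for the number of
  components, and no functional enrichment — these are upstream or
  downstream of this package's scope.
* The missing-fraction threshold is interpreted per gene; if a dataset's
  documentation intends a whole-matrix budget, apply the filter with an
  adjusted threshold.
* Ward clustering of very large gene sets is O(n²) in memory via the
  pairwise distance matrix; subsample or pre-filter for matrices far
  beyond ~30k genes.
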