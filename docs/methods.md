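# Methods

This note documents the statistical procedures the package implements, the
conventions it fixes where the field leaves choices open, and what the
synthetic-data generator does and does not emulate.

## Quality control

Cell filtering follows a two-pass scheme on per-cell summaries (UMI total,
detected genes, MT%, Ribo%, externally supplied doublet score):

1. Pass 1 removes cells with fewer than 1,000 UMIs or fewer than 500
   detected genes.
2. Pass 2, on the survivors, removes cells with fewer than 5,000 UMIs, cells
   in the top 0.1% by UMI total, doublet scores over 0.2, MT% over 10, or
   Ribo% over 40.

All inequalities are strict, so boundary values (exactly 5,000 UMIs, a
doublet score of exactly 0.2) are retained. The top-0.1% rule is read as a
cell-count rule — the ceil(f·N) highest-UMI cells of the population entering
pass 2 are removed, with ties broken by input order (later rows removed
first) — rather than as a percentile-value threshold; the phrase "top 0.1%
of the total cells" counts cells. Both readings are defensible; the
implementation exposes the rule list so the alternative can be substituted.
Within a pass, rules are conjunctive and therefore order-invariant, except
that the top-fraction rule is always evaluated on the population entering
its pass.

Gene retention has two stages: "primary" keeps genes on chromosomes 1–22,
X, Y and MT (dropping unplaced scaffolds); "embedding" keeps protein-coding
and lincRNA biotypes and drops sex-chromosome genes (which otherwise encode
donor line rather than cell state in a pooled two-line design).

Doublet-enriched clusters are flagged when a cluster's mean doublet score
exceeds `score_factor` (default 2) times the median of per-cluster mean
scores. This reconstructs a step usually done by manual inspection of the
score distribution; the factor-over-median rule is conservative (robust to
one inflated cluster dragging the centre) and user-overridable.

## Normalization and embedding

Counts are normalized per cell to a scale factor of 10,000 and
log-transformed: `x = ln(1 + 10,000·c/total)`. For integer counts with no
genes dropped, per-cell `sum(expm1(x))` equals the scale factor exactly;
this conservation is an invariant the tests enforce at 1e-6 relative.

Highly variable genes are ranked by variance-stabilized dispersion: on the
expm1 scale, a lowess trend of log10(variance) against log10(mean) across
genes gives the expected standard deviation at each mean; each gene's
values are standardized by that expectation (clipped at sqrt(n_cells)) and
genes are ranked by the variance of the standardized values. This is the
vst convention; a per-bin z-score of raw dispersion was considered and
rejected because co-regulated high-variance genes that crowd the top mean
bins are then standardized against each other and vanish from the ranking
(we observed planted marker recovery drop from 50/50 to ~20/50, and
scanpy's binned "seurat" flavor shows the same failure mode on such data).

Covariates (for example a cell-cycle score) are removed per gene by
ordinary least squares with intercept; residuals are then standardized to
mean 0, sd 1 (sample sd, ddof=1). Residuals are exactly orthogonal to the
covariates (checked at 1e-10). Genes with zero residual variance become
all-zero rows and are flagged rather than dropped, keeping the gene universe
stable. The module score used for cell-cycle indices is a bin-matched
contrast: genes are binned into 25 equal-frequency bins of mean expression
and each set gene contributes up to 100 control genes sampled from its bin,
excluding the set itself (a set that dominates its bins would otherwise act
as its own control and null the score). Score = mean(set) − mean(controls),
seeded and deterministic.

PCA uses exact SVD of the centered matrix with 30 components by default.
Each component is oriented so its largest-magnitude loading is positive,
removing the SVD sign ambiguity so repeated runs are bit-identical.
Requesting more components than the data rank (+1 for centering) is an
error. Clustering builds a Euclidean kNN graph and delegates community
detection to leidenalg's RB-configuration partition (equivalent to
modularity at resolution 1), seeded; coincident points are connected
pairwise so duplicated cells always co-cluster. Community detection is
deliberately delegated — it is standard machinery, not a contribution of
this package.

## Reciprocal NNLS cell-type correspondence

Cluster profiles are per-cluster means of log-normalized expression,
optionally after downsampling large clusters without replacement (one
seeded draw per cluster, in sorted label order; defaults 200 cells per
query-side cluster and 500 per reference-side cluster) so that cluster size
does not weight the fit.

For a target cluster `a` in dataset A with profile `T_a`, the model is

    T_a = β0_a + β_1a · M_b,   β_1a ≥ 0, β0_a free,

where `M_b` stacks all cluster profiles of dataset B. The free intercept is
implemented by augmenting the design with +1 and −1 constant columns inside
a single NNLS solve (β0 = b⁺ − b⁻), keeping one canonical solver. The fit
is restricted to the union of the target's 1,500 most highly expressed
genes and its 1,500 most highly specific genes, where specificity(g) =
target(g) / (mean over the target's own dataset's clusters + 1e-8) and
genes absent from the target are excluded from the specificity ranking.
Rankings use the target's mean log-normalized values (normalization
precedes averaging, so this is the natural scale); ties break by gene
order. Both orderings — expressed and specific — follow the conventions of the
atlas literature this statistic comes from.

Directions are then swapped (each B cluster regressed on all A profiles)
and the two directed coefficients for a pair (a, b) combine into

    β = 2 (β_ab + 0.01)(β_ba + 0.01),

which is strictly positive (floor 0.0002) and large only when each cluster
specifically predicts the other. For display, each row of the combined
matrix is divided by its maximum ("max" scaling; z-scaling is exposed as an
option). The solver is verified against an exhaustive active-set oracle
(all 2^p supports, feasibility-filtered) on overdetermined instances with
up to 8 columns; underdetermined fits have non-unique optima and are
outside the verified envelope.

Cross-species comparisons collapse counts onto homologous target genes
before normalization: a possibly many-to-many two-column table maps source
to target ids, each target's count is the sum of its mapped sources' counts,
and the collapsed matrix is re-log-normalized.

## kNN in-silico staging

Queries and reference are embedded jointly: concatenate cells over the
shared gene universe, select HVGs on the concatenated matrix, scale, PCA to
30 dimensions. Anchor-based batch correction is intentionally not
reimplemented — the staging statistic, not the batch correction, is the
defined computation here — and externally corrected coordinates can be
supplied instead.

Two neighbor modes, both Euclidean in PC space with ties broken by
reference cell order:

- `per_stage_pool` (staging, k=15): for each query cell, the k nearest
  reference cells are found within each stage separately; the per-stage
  candidates are pooled and the k globally nearest of the pool are kept.
  The stage fractions of that final set are the cell's staging
  distribution. The merge rule (pool then global top-k) is one of two
  defensible readings of "k nearest within each stage"; the plain global
  mode is provided as the alternative and the two coincide for a
  single-stage reference.
- `global` (cell-type composition, k=20): plain kNN over all reference
  cells.

Fractions are multiples of 1/k and sum to 1. Per-group summaries average
member cells' fraction vectors (renormalized), report the modal label
(argmax, ties by label order) and the top-5 most abundant labels. The
implementation is tested to be bit-identical to a brute-force all-pairs
distance computation with explicit lexicographic sorting.

## Downstream analyses

**PC1 axis analysis.** A cell subset (e.g. the neural-tube-related types) is
re-embedded with its own HVGs/scaling/PCA; every gene of the log-normalized
matrix (not only HVGs) is correlated with PC1 (Pearson). p-values come from
the t-transform of r with n−2 df and are Benjamini–Hochberg adjusted; the
significance convention (Pearson + BH at 0.05) is a reconstruction, as is
reporting constant genes with r = 0 and a flag instead of dropping them.

**qPCR normalization.** Relative expression is 2^−ΔCt against the
housekeeping gene (GAPDH) per segment; each gene is then z-scored across
the anterior/middle/posterior segments (sample sd). The 2^−ΔCt transform is
the standard reading of "normalized to GAPDH"; a linear −ΔCt option is
exposed because the z-scores are not invariant across monotone transforms.
Row z-scores sum to zero, are invariant to adding a constant to a gene's Ct
row, and genes undetected in any segment are emitted as missing rows;
zero-sd rows become zeros with a flag.

**Line-of-origin composition.** Per cell type and overall, fractions of
cells per donor-line assignment ({lineA, lineB, doublet, unassigned}), with
a confident-only view renormalized over the two lines.

## Synthetic data

The generator plants everything the analyses are asked to recover. Genes
get chromosome labels (exact-count proportions: MT fraction, ~5% X, ~2% Y,
rest autosomal), biotypes (protein-coding fraction, half the remainder
lincRNA, rest "other") and ribosomal flags (RPS/RPL symbols). Expression is
negative binomial (Gamma–Poisson) with a single shared dispersion around
cell-specific means

    λ_gc = libsize_c · softmax_g(base_g + type_effect·marker_gc
                                 + stage_effect·stage_c·gradient_g + batch_g),

with lognormal library sizes, disjoint marker sets per type, a fixed random
gene direction for the stage gradient, and an independent batch shift per
dataset in paired mode. Doublets are sums of two emitted singlet cells of
distinct types (parents recorded), with simulated doublet scores (means
0.05 vs 0.5, sd 0.05, truncated to [0, 1]) chosen so the 0.2 threshold
separates the populations — scores are simulated because their computation
is an external tool's job. A dedicated QC fixture constructs cells at every
filter boundary (999/1,000/4,999/5,000 UMIs; 499/500 genes; 9.9/10.1 MT%;
39/41 Ribo%; scores 0.19/0.20/0.21) with exact integer allocations and the
intended outcome recorded per rule.

Defaults are one decision, made once: 2,000 genes, 10 types × 200 cells,
marker log-fold 2 with 50 markers/type, NB dispersion 2 (BCV ≈ 0.7),
lognormal library sizes around 20,000 UMIs (σ = 0.35) so most cells clear
the 5,000-UMI floor, 5% doublets. Stage effects enter linearly in logit
space; large values (≳2 per step) saturate the softmax and compress later
stages onto each other, so gradient-linearity checks use effects ≤1 while
local-neighborhood staging tolerates saturation.

What the generator does **not** emulate: gene–gene correlation beyond the
planted type/stage/batch structure, ambient RNA, UMI saturation, empirical
mean–variance relationships of specific platforms, or batch effects with
structure other than a global log-mean shift. Passing the planted-recovery
tests therefore demonstrates correctness of the statistics under their own
assumptions, not robustness to every artifact of real droplet data.

## Problem sizes and determinism

The verification suite runs at desk scale: NNLS oracle instances up to
8 × 50, correspondence recovery on 10-type pairs of 2,000 cells × 2,000
genes over 5 seeds, staging on a 2,000-cell 4-stage reference with 200
held-out queries, and a 1,000-cell QC fixture. These sizes were chosen so
the full pipeline exercises every code path in seconds while leaving the
statistics comfortably clear of their thresholds. Every stochastic step
(simulation, downsampling, control-gene sampling, clustering) takes an
explicit seed; repeated runs are bit-identical.

## Known limitations

- The doublet-cluster flagging rule reconstructs a manual-inspection step;
  its factor-over-median default is a heuristic.
- NNLS coefficient uniqueness (and hence oracle equivalence) requires more
  selected genes than clusters — always true in practice, not enforced.
- The per-stage-pool merge rule and the top-0.1% cell-count reading are
  documented choices between textually admissible alternatives.
- The joint embedding substitutes plain joint PCA for anchor-corrected
  integration; with strong batch effects between query and reference the
  staging distribution will reflect batch as well as stage.
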