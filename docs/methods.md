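# Methods

This note documents the models, procedures, parameter choices and known
limitations behind homomap, in the order the workflow runs.

## Synthetic two-species model

The generator exists so every downstream stage can be validated against a
known ground truth; it emulates the statistical structure cross-species
comparison relies on, not any particular organism.

Ancestral per-gene baseline means are log-normal (σ = 1). Each cell-type
up-regulates its own disjoint block of `markers_per_type` genes by
`2**log2_effect`. Species B reuses species A's programs for the first
`n_shared` types through the true one-to-one ortholog map, multiplied by
an independent log-normal factor per (type, gene) (σ = 0.25) and a
species-level log-normal baseline perturbation (σ = 0.2) — programs are
copied then perturbed rather than mixed, so "homologous" has a crisp
ground truth. UMI counts are gamma-Poisson (negative binomial) with
dispersion θ (default 10; θ = ∞ gives Poisson) around per-cell log-normal
library sizes (mean 3000, CV 0.3), the standard UMI noise model. All
generators are pure functions of (config, seed).

Defaults are the study conditions every default test runs under:
2000 genes, 10 types per species with 7 shared, 100 cells per type,
40 markers per type at log2 effect 2.0, 30% duplicated ortholog entries,
5% source noise, a 30×30 spot grid with 4 regions and 8 cells per spot on
average (spots sum the raw counts of Poisson-many reference cells drawn
from per-region Dirichlet mixtures over cell-types).

**Duplicated orthologs.** A `dup_fraction` of genes carries a second,
lowly expressed co-ortholog (baseline 0.05× the primary, no cell-type
program), mimicking retained duplicates after a genome duplication. Its
candidate table rows additionally lose each annotation source with
probability `paralog_annotation_dropout` (default 0.3), reflecting the
patchier annotation of minor paralogs; without this, primary and
duplicate rows are source-for-source identical and resolution of
duplicates degenerates to the UMI tie-break alone. The 0.05× expression
ratio makes the UMI tie-break decisively favor the expressed copy.

What the generator does *not* emulate: gene-gene correlation beyond
cell-type programs, batch effects, ambient RNA, doublets, per-gene
dispersion trends, or spatial autocorrelation beyond rectangular region
blocks. Passing tests therefore demonstrate correctness of the
procedures under a clean, known-truth regime — not robustness to every
artifact of real atlases.

## Ortholog resolution

Candidates come from five source fields per query gene. "Consistency" is
the number of sources exactly equal (case-insensitive) to a candidate
symbol. Per query gene the most consistent candidate is claimed
(lexicographic tie-break); per human symbol the most consistent claimant
is kept, ties broken by greatest `umi_total`, then by query-gene sort
order — a deterministic fourth level the underlying rule leaves
unspecified. The result is strictly one-to-one and invariant to row
order. The UMI tie-break sums whatever expression matrices are supplied
with equal weight.

## Markers and profiles

Expression is library-size normalized to 10,000 counts per cell and
log1p-transformed (a documented stand-in for variance-stabilizing
regression, which is out of scope). Marker detection is a one-vs-rest
two-sided Wilcoxon rank-sum per group on normalized expression, using the
normal approximation with tie and continuity correction — identical to
R's `wilcox.test`/scipy's asymptotic method, chosen because it vectorizes
over thousands of genes. The exact enumeration test lives only in the
test oracles; the approximation agrees with it to < 0.02 at group sizes
≤ 8 over the small-to-moderate p range, drifting up to ~0.05 only near
p = 1 where no marker call is ever made. log2 fold changes compare
in/out means of de-logged normalized values with ε = 1e−9; Bonferroni
correction multiplies by the number of (gene, group) tests performed.

Group profiles are per-group means of library-size-normalized
(linear-scale) expression. Profile normalization is y = log(x + 1) + 0.1
(natural log), then division of each gene column by its mean across
groups, making every gene's mean exactly 1: genes contribute comparable
rank information regardless of absolute expression level. An all-zero
gene maps to the constant 1 — correlation-neutral by construction.

Conserved-marker intersection across ≥ 2 species uses relaxed thresholds
(adjusted p < 0.05, log2FC > 0, expressed in > 10% of cells); when several
genes of one species share a human symbol the greatest-log2FC gene
represents it, so this step accepts many-to-one gene→symbol maps. The
shared-marker fraction is directional (a → b) by default; the symmetric
construction is not uniquely determined, so direction is the caller's
choice.

## Correlation mapping

Spearman ρ between group profiles is computed over ortholog pairs that
are markers of at least one group in each species (≥ 5 required). The
one-sided (greater) p uses the t approximation with n − 2 degrees of
freedom. The permutation null independently shuffles each gene column of
the *first* species' profile across its groups (the second species held
fixed) and counts permuted ρ **strictly greater** than observed, so the
minimum attainable p is 0; a (count+1)/(n_perm+1) smoothing variant is
available behind a flag but off by default. Both criteria are Bonferroni
corrected over all group pairs, and a pair is significant only when both
adjusted values fall below α = 0.05. Per-gene independent shuffling (not
joint row permutation) is the implemented reading of "shuffling values
across cell-types"; the joint alternative would preserve gene-gene
correlation under the null and is noted as future work.

## kNN-graph mapping

The joint embedding expresses both species in the shared-ortholog feature
space (species A translated through the resolved map), jointly
log-normalizes, standardizes each feature, optionally scales features by
per-pair weights (e.g., protein-sequence similarity), and projects onto
`n_dims` = 30 principal axes via a full SVD with a fixed sign convention
(largest-|loading| coordinate positive), so results are deterministic
given input order. This is a deliberately simple, transparent integration;
graphs produced by heavier sequence-aware integration tools can be
imported from a TSV edge list and scored identically.

The kNN graph is exact (all-pairs Euclidean distances, k = 20 total
neighbors per cell, distance ties broken by node index). Only
cross-species neighbors are scored. The score is symmetrized over both
directions and divided by |a| + |b|, so it is well defined for both
species' rows; a strict one-directional variant sits behind
`symmetric=False`. Each cell's cross-species neighbors are counted in
exactly one (a, b) cell of the matrix.

Significance permutes labels within each species with the graph fixed
(default n_perm = 1000) and uses `≥` in the exceedance count — the
conservative choice — with q_perm = 0 as the significance criterion.
Each pair is compared to its own permuted distribution by default; a
`pooled-row` mode compares against the row's permuted maxima instead.
Reciprocal top hits require a strict argmax in both directions; ties
yield no flag.

Driving genes operationalize "contributes positively to the
cross-species correlation" as a positive centered-rank product over the
shared DEG space, restricted to genes that are markers of both members,
returned unabridged in decreasing contribution order. The rank-product
sign agrees with a re-ranking leave-one-out Δρ oracle where contributions
are decisive (moderate overall ρ); at ρ near 1 the leave-one-out sign of
near-zero contributions is essentially arbitrary, so the two definitions
are not interchangeable gene by gene.

## Downsampling benchmark

Each cell loses exactly `round(fraction × total)` UMIs (half-to-even) by
a multivariate hypergeometric draw over its genes — exact
without-replacement removal, not binomial thinning — and `n_drop` = 3
whole cell-types are removed so the comparison is not one-to-one.
Original labels are retained on surviving cells (the protocol compares
known same cell-types; no re-clustering). The method's score matrix is
flattened row-major against the identity indicator and summarized by
squared Pearson correlation, which is invariant to affine rescaling of
the scores; a constant matrix yields a missing value. The benchmark
dataset in tests and the acceptance script uses ten types (the default
type count), 1000 genes, 40 markers/type at log2 effect 3 with Poisson
noise: with a 7 × 10 matrix, a label-blind method's chance R² is
~1/(n−1) ≈ 0.014, low enough to separate cleanly from real methods.

## Region tools

The Rand index is unadjusted — the plain fraction of item pairs on which
two partitions agree — with a chance-corrected variant offered
separately. Region pseudobulk sums raw counts over spots per region;
regions then play the role of cell-types so both mapping routes apply
unchanged. Abundance post-processing rounds half-to-even and assigns one
cell at the pre-rounding argmax type to empty spots (first type, with a
warning, if the raw row is all zero).

Clustering-parameter selection clusters principal components (30 PCs)
with an exact symmetrized kNN graph and Leiden under the
resolution-scaled modularity objective. The grid is
(graph n_neighbors × resolution): the nonlinear-projection stage the
original selection tuned is out of scope, so the grid substitutes the
graph neighborhood size while preserving the selection rule. Each of
`n_boot` (default 100) bootstraps reclusters an 80% subsample from
scratch (PCA recomputed, so bootstraps are independent); pairwise
co-clustering frequencies over bootstraps where both cells were sampled
define the dissimilarity 1 − frequency; each cluster's score is the
median silhouette width of its cells (singletons recorded as missing,
never fabricated). The 95% lower confidence bound is the 2.5% quantile
of 1000 bootstrap resamples of the per-cluster scores' median — the
named interval comes without a recipe, so this is the documented choice.
Selection: with T the highest lower bound across combinations, choose
the combination with the most clusters whose score exceeds T (ties:
fewest clusters, then grid order).

## Downstream statistics

Welch's t uses the Satterthwaite degrees of freedom; it reduces to the
classical equal-variance t when variances and sample sizes are equal. A
metric constant across all pairs is reported as t = 0, p = 1 rather than
an error. The gene-class χ² is Pearson's test on the strata × 3 table of
**rounded mean** counts of transcription factors, neuromodulatory ligands
and receptors — means are rounded (half-to-even) to satisfy the count
requirement, and "other" is excluded from the test though kept in the
descriptive table; raw summed counts are available via `use_means=False`.

## Problem sizes and numerical conventions

Tests and the acceptance script run the full default study conditions for
homology recovery (2 × 1000 cells, 2000 genes, n_perm = 200) and smaller
but structurally identical configurations elsewhere (e.g., 300 cells ×
300 genes for clustering selection with n_boot = 25, 50 replicates of
4 × 4-type null graphs for calibration) — sizes chosen so the whole suite
exercises every code path at full statistical resolution in about a
minute. Rounding is half-to-even throughout; all randomness flows through
`numpy.random.default_rng` seeds; PCA signs are fixed by the
largest-loading convention; distance and argmax ties break by index or
sort order everywhere, so every result is reproducible bit for bit.

## Limitations

The integration stand-in is plain joint PCA: it does not model protein
sequence divergence (weights can inject it) and will underperform on
species pairs whose shared signal is not linearly accessible. The
permutation nulls treat cells as exchangeable within species, ignoring
batch structure. The synthetic generator's idealizations (above) mean
quantitative performance numbers (recovery rates, benchmark R²) describe
the clean regime, not any particular real dataset.
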