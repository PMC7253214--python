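# Methods

`hybcoex` re-implements, as a tested pipeline, a consensus weighted
gene-coexpression analysis of testis expression in subfertile hybrid house
mice: two mapping cohorts (an F2 laboratory cross and offspring of wild-caught
hybrid-zone mice) share a consensus "fertile" network, and the question is
which coexpression modules fall apart in subfertile animals, and which genes
drive the collapse.  This note records the model, the defaults, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Preprocessing

Raw probe intensities are background-corrected with the "half" rule
(`max(F - B, 0.5) + offset`, offset 50), which floors negative subtractions
and stabilises the variance of dim probes.  Probes are kept only if they are
at least 10% brighter than the 98th percentile of the negative-control probes
on at least 10% of arrays; the threshold is computed per array on the
background-corrected scale (the alternative — thresholding before the offset —
differs only by a constant and was not taken).  Values are then
log2-transformed and quantile-normalized; the log transform precedes
normalization, the standard order for intensity data.  Ties within an array
receive the mean of the reference values at the tied rank positions, which
makes the map idempotent.

Known batches are removed with a parametric empirical-Bayes location/scale
model: per gene the data are standardized by the batch-design fit, per-batch
means and variances are shrunk toward a normal and an inverse-gamma prior
whose hyperparameters are fitted by method of moments across genes, and the
coupled posterior equations are iterated to convergence.  No biological
covariates are protected; in particular fertility class is *not* in the
model, so any fertility signal confounded with batch is attenuated — a
deliberate caveat, since class labels are themselves derived downstream.
With a single batch the step is the identity.  Zero-variance genes pass
through unadjusted.

PCA is the SVD of the probe-standardized matrix (each probe centred, unit
variance); explained fractions are `s_k^2 / sum(s^2)` and component signs are
fixed by the largest-magnitude loading.  A MAD rule flags samples more than
`k_mad = 6` MADs from the median on PC1 or PC2 — a deterministic stand-in for
by-eye screening.  The pipeline *records* the flags but does not remove
samples: on data with a genuine aberrant-expression group the rule flags
exactly that group, and deleting it would remove the biology under study.
Callers who want removal can act on the recorded list.

## Fertility and expression classes

Two fertility proxies are used: relative testis weight (testis weight / body
weight, g/g) and sperm count.  Pure-subspecies samples — pooled across both
subspecies by default, since a single fertile band is used throughout; a
per-subspecies switch exists — define a mean, a sample SD (n−1) and a min–max
range per phenotype.  Hybrids with either phenotype outside the range are
`subfertile`; with both phenotypes within 1 SD of the mean, `fertile`;
otherwise `intermediate`.  Boundary values count as within.  Subfertile
samples whose genome-wide PC1 score falls strictly outside the [min, max]
interval spanned by fertile hybrids and pure samples are `SFAE` (subfertile
aberrant expression); the rest are `SFNE`.  The reference group for the
interval is the union of fertile hybrids and pure samples.

## Consensus network

Within each cohort's fertile samples, the signed adjacency is
`a_ij = ((1 + cor_ij) / 2)^beta` with Pearson correlation and soft power
`beta = 5` (a diagnostics table with scale-free fit R² and mean/median
connectivity supports choosing the lowest beta at which median connectivity
plateaus, relative tolerance 5%; the final value is a config entry).  Before
network construction, probes with soft connectivity at or below the median —
computed on the pooled fertile samples — are discarded, halving the probe
set.

Adjacency is converted to topological overlap,
`TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`L_ij = Σ_u a_iu a_uj`, and the per-cohort TOMs are calibrated by a single
multiplicative factor equating their 0.95 off-diagonal quantiles to the
across-cohort mean; the consensus TOM is the componentwise minimum.
`1 − TOM` is clustered by average linkage (UPGMA, via scipy).

Module detection is a re-implementation of the adaptive tree-cut idea, not a
port of the reference algorithm, and equivalence with it is not claimed —
the acceptance standard is planted-module recovery.  The cut height is
placed in the widest gap of the sorted merge heights, searched above a floor
quantile that drops as `deep_split` grows (`deep_split = 0`, the default,
searches the upper half); this separates the within-branch from the
between-branch height regimes whenever the dendrogram has genuine branch
structure.  Branches below `min_module_size = 50` start unassigned; a medoid
stage then assigns each unassigned object to its closest module if its
medoid dissimilarity lies within that module's own radius (the maximum
member–medoid dissimilarity).  Labels are ordered by decreasing size;
label 0 is the unassigned bin.

Module eigengenes are first principal components of the member-standardized
expression, unit variance, oriented so the mean member kME is non-negative.
Modules whose consensus eigengene dissimilarity — the max over cohorts of
`1 − cor(ME_a, ME_b)` — falls below 0.2 are merged iteratively (average
linkage over the module dissimilarity, cut at 0.2, eigengenes recomputed
each round).  kME is the Pearson correlation of a probe with an eigengene.
Module–trait associations are Pearson r with the exact t-based two-sided p
(`t = r sqrt((n−2)/(1−r²))`), computed over all hybrid samples with pairwise
deletion of missing traits.

## Module preservation

Seven statistics per module: four density statistics evaluated in the test
cohort (mean pairwise correlation, mean signed adjacency, proportion of
variance explained = mean kME², mean signed kME) and three connectivity
statistics comparing cohorts (correlations of intramodular connectivity, of
kME, and of the pairwise correlation pattern).  The permutation null draws
random same-size gene sets from **all** network probes, module genes
included — the cited methodology's default, and the only choice that keeps
the null well defined for modules covering a large share of the network.
Per statistic `Z = (obs − mean_perm)/sd_perm`; `Z_density` and
`Z_connectivity` are medians of their groups; `Z_summary` is their mean, with
≥ 10 / 2–10 / < 2 read as strong / weak / absent preservation.  The median
rank averages the median observed-statistic ranks of the density and
connectivity groups (rank 1 = most preserved).  A second permutation run
gives one-sided p-values `(1 + #{perm ≥ obs}) / (n_perm + 1)`; a module
counts as significantly preserved only when all seven p < α = 0.05, with no
multiple-test correction (a Bonferroni switch exists).  Defaults: 500
permutations for Z, 1000 for significance.

A structural property of this null is worth recording: random mixed gene
sets inherit reproducible structure from the modules they straddle, so the
null distributions of the *connectivity* statistics are high wherever few,
large modules dominate the network.  Truly preserved small modules
(≲ 150 genes at ~100 samples per cohort) then sporadically fail one
connectivity p-value — as several modules do in real data.  The calibration
experiment therefore plants modules of 150–300 genes (see below).

## Differential correlation

Per gene pair, the Fisher-z difference
`z = (atanh r_test − atanh r_ref) / sqrt(1/(n_test−3) + 1/(n_ref−3))` with a
two-sided normal p and a loss / gain / reversal class; |r| is clamped at
1 − 1e−12 before atanh.  Per gene, the statistic is the median over module
partners of `log2(max(|r_test|, floor) / max(|r_ref|, floor))` with floor
0.01 guarding against division by near-zero reference correlations.
Significance comes from permuting cohort labels across the pooled samples —
jointly for all genes, preserving the gene–gene dependence — with a
two-sided empirical p (add-one rule, 100 permutations by default).  A
significant gene is `loss` when its median LFC is negative without a sign
flip of the median partner correlation, `reversal` with a flip.  Note that a
pure sign reversal leaves |r| unchanged, so a reversal at a small planted
fraction is intrinsically hard for an |r|-based statistic; the benchmark
quantifies sensitivity for decoupling, where the statistic is designed to
work.

## Hubs and enrichment

Hubs per module are the union of (a) probes whose kME, combined across the
two cohorts by `min` (both cohorts must pass; `mean` available), reaches
0.85 and (b) the top 5 probes per cohort by intramodular degree, where degree
counts module partners with TOM ≥ 0.1 (ties: higher summed TOM, then probe
id).  A gene is a hub iff any of its probes is.

Gene-set over-representation uses the one-sided hypergeometric (Fisher)
tail with Benjamini–Hochberg correction per annotation category (terms,
cell types, QTT sets); sets are intersected with an explicitly supplied
universe first and only sets of 11–499 genes after intersection are tested
("more than 10 and fewer than 500").  Hub enrichment in genomic region sets
(sterility loci, trans-eQTL hotspots) uses 10,000 random same-size draws
from the universe; enrichment is called when the observed count equals or
exceeds the 95% null quantile (and is nonzero), with an add-one empirical p
reported alongside.  Both the all-expressed and the module-assigned
universes are exercised.  Interval overlap is 0-based half-open:
`max(starts) < min(ends)` on the same chromosome.

## Synthetic data

The generator is the package's ground-truth instrument.  On the log2 scale,
for gene g in module m and sample s:

    x_gs = mu_g + lambda_g f_ms + c_g A_s + gamma_gb + delta_gb eps_gs

with factor scores f ~ N(0,1) drawn independently per population from the
same architecture (two cohorts, one consensus), loadings |lambda| ~
U(0.2, 0.98) with one orientation sign per module, noise sd 0.4, per-batch
location effects gamma ~ N(0, 0.3²) and noise-scale factors delta ~
U(0.8, 1.25), and an aberrant-expression axis c (c ~ N(0, 0.4²) on 40% of
genes) switched on at A = 5 only in planted SFAE samples.  Disruption in
subfertile samples either *decouples* a fraction of a module's genes
(factor term replaced by an independent same-variance draw) or *reverses*
it (loading negated).  Defaults: 15 modules sized U[50, 300] sorted
descending (the phenotype-driving and disrupted low-index modules are the
large ones, as in the real data, where the phenotype-correlated modules are
the largest), 400 background genes, 10% duplicate probes (same structural
terms, independent noise), 100 negative-control probes, class sizes
102/92/69/37 (F2 fertile/intermediate/SFNE/SFAE), 79/41/38/17 (HZ), and
16 + 16 pure samples.  The loading spread and noise level were fixed at
design time so that the planted architecture supports the statistics built
on it: top-decile-loading genes exceed the kME 0.85 hub threshold
(`0.9/sqrt(0.9² + 0.4²) ≈ 0.91`), and intramodular connectivity has enough
true spread for the inter-cohort connectivity statistics to be informative.

Phenotypes are `Σ_m w_m f_ms + noise`, rank-affinely rescaled per planted
class so that fertile hybrids land within 1 SD of the pure mean,
intermediates stay inside the pure range while exceeding 1 SD, and
subfertile hybrids fall below the range (pure phenotype draws are jittered
normal quantiles, guaranteeing a usable range from 32 samples).  Within a
class the map is monotone, so module–trait correlations keep their planted
sign.  Raw-intensity fixtures are produced by exponentiation plus an
additive background (N(60, 5²)); negative controls are low-intensity
(log2 ≈ 5), so the expression filter's thresholds land between controls and
genes.

Synthetic annotations place genes uniformly on a 20-chromosome genome;
region sets include each gene with probability 0.10, raised to
`multiplier × 0.10` for top-decile-loading genes of target modules; gene
sets hit configured Jaccard overlaps with chosen modules
(`overlap = 2Kj/(1+j)` at matched size), plus size-matched random controls.

What the generator does *not* emulate: array spatial artifacts, dye or GC
bias, probe cross-hybridization, heavy-tailed intensity noise, correlated
background genes, overlapping modules, or hidden (unrecorded) batches.
Passing the benchmark therefore shows the machinery is correct and
calibrated under a linear-Gaussian factor model with known batches — not
that the biological conclusions of any particular real dataset are right.

## Benchmark problem sizes and experiment designs

The planted-recovery benchmark uses the default generator (≈3,000 probes
before filtering, ≈1,900 network probes after, 181 fertile samples across
the two cohorts) and asks for adjusted Rand index ≥ 0.8 against the planted
modules and planted-sign module–trait correlations at p < 0.01 — observed
ARI is ≈ 0.99.  The preservation-calibration experiment
(`preservation_calibration_config`) plants modules of 150–300 genes, one of
them fully decoupled, and switches the SFAE axis off so module disruption
is the *only* planted difference between fertile and subfertile samples —
with the axis on, its genome-wide correlation shift genuinely perturbs
non-disrupted modules in the pooled subfertile group, which is realistic
but would conflate two mechanisms in one calibration.  Null p-value
uniformity is checked on random gene sets in pure-noise cohorts (80 probes,
199 permutations, 100 replicates, per-statistic KS).  Differential
correlation is benchmarked with a half-decoupled module against the SFNE
group (the axis-free subfertile class).  Tests run permutation counts of
100–200 where the estimate, not the tail resolution, is under test; the
acceptance script uses the full 500/1000 defaults.

## Numerical choices

Correlations are clipped to [−1, 1]; TOM to [0, 1].  Eigengene extraction
uses the smaller Gram matrix (samples or genes) and `eigh`.  UPGMA
tie-breaking follows scipy's deterministic nearest-neighbor chain.  All
randomized stages derive their generator from blake2b(root seed, stage
name) — stable across platforms, always < 2³¹ — so a root seed fixes every
stage, and two runs with the same config and seed produce byte-identical
output tables (floats are written with 17 significant digits and re-parsed
by exact conversion).  Degenerate inputs: zero-variance probes are dropped
(correlation, PCA) or given kME 0; a zero permutation SD yields a flagged
infinite Z; empirical p-values use the add-one rule and can never be 0.

## Known limitations

Full dense matrices bound the network size (memory ≈ n² × 8 bytes per
matrix; ~25k probes is the practical ceiling, with no block-wise variant).
The tree cut assumes a height gap between within- and between-branch
merges; on structureless data it degenerates gracefully (few or no
modules) but is not a substitute for the reference implementation's
fine-grained splitting at `deep_split > 0`.  The preservation p-values
inherit the all-probes null described above.  Reversal detection at small
planted fractions is limited by the |r|-based statistic.  The pipeline
assumes batches are known; no surrogate-variable estimation is attempted.
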