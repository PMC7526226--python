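# Methods

This note documents the statistical models, default parameters, and
design choices behind each stage of the pipeline, and what the
synthetic data do and do not establish about behavior on real data.

## Study design and data model

The unit of analysis is a feature-by-sample matrix (RNA-seq counts or
LFQ intensities) over a factorial design: genotypes (a control driver
line and one or more Tau-expressing lines) crossed with ordered age
levels (defaults 1, 10, 20 days) and a few replicates per cell
(default 3). Age is always treated as a categorical factor, never a
slope, because aging effects on brain expression are strongly
non-linear across these timepoints. Missing proteomic values are NaN
throughout; zero is a measured value, not a missingness code.

## Synthetic data generator

The generator exists so that every downstream stage has testable ground
truth. Transcript counts are negative binomial with Var = μ + αμ²:
per-gene baselines are log-normal (median ≈ 400 counts, log-sd 1.2,
spanning roughly 10–10⁵ — the dynamic range of a moderately deep bulk
library after low-count filtering), per-gene dispersions log-normal
around 0.05 (log-sd 0.5), matching the within-genotype variability of
well-replicated inbred fly lines; library depths vary with 20% CV. A
fraction of genes (default 10%) receives a genotype log2 fold-change
with |LFC| ~ N(1.5, 0.5) and random sign; 30% receive independent
per-age-level offsets (sd 0.75 log2 units). Published counterparts of
these effect-size distributions are not available, so the defaults are
conventions chosen once to be realistic for a strong neurodegeneration
phenotype; they are configurable but the defaults define the test
conditions everywhere.

The proteome is generated from the transcriptome: each protein's latent
log2 intensity tracks its transcript's log2 counts with slope +1
(concordant, default 60% of genes), −1 (discordant, 25%), or varies
independently (15%), plus Gaussian noise (sd 0.5). These fractions
encode the empirical observation that roughly half of transcript
changes fail to propagate to protein. Missingness combines an MNAR
component — a logistic function of latent intensity centered at the
15th percentile (the detection limit), steepness 1.5 per log2 unit —
with 2% uniform MCAR dropout. Intensities are exponentiated and scaled
to a grand median of 10⁶ to mimic raw LFQ magnitudes; the scale is
arbitrary and documented as such.

What the generator does **not** emulate: peptide-level identification
and razor-peptide ambiguity, batch structure between control sets,
sample heterogeneity of the kind that suppresses mid-series
cross-sectional counts, correlated gene modules beyond what genotype-
and age-effects induce, and transcript–protein temporal lags. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the declared model, not robustness to those
real-data complications.

## Differential expression

Counts are filtered at mean < 50 across the samples of the comparison
(inclusive boundary: mean exactly 50 is kept). Size factors are
median-of-ratios: per-gene geometric means over samples define
reference ratios, and s_j is the median ratio over the genes positive
in every sample. The GLM is negative binomial with log link; size
factors enter as fixed offsets; treatment coding uses the control
genotype and earliest age as references. Coefficients are estimated in
natural log and reported as log2 (division by ln 2).

Fitting is IRLS vectorized across genes (the design matrix is shared;
per-gene weighted normal equations are solved in a batched linear
solve). Dispersion is per-gene maximum likelihood on the Cox–Reid
adjusted profile likelihood (the −½ log det X'WX term corrects the
downward bias of plain ML when the mean model consumes 4 of 18
degrees of freedom), with a method-of-moments initializer, two
alternating rounds of mean-fit and dispersion-fit, a golden-section
search on log α over [10⁻⁸, 50], and no shrinkage across genes. The
absence of empirical-Bayes dispersion moderation is deliberate: the
package validates by simulation properties (calibration and recovery),
not by replicating any particular tool's output.

Wald statistics are referred to a t distribution with residual degrees
of freedom n − p (and the joint interaction statistic to F with
(df, n − p)) rather than the asymptotic normal/χ². At 2–3 replicates
per cell the asymptotic reference is anti-conservative (empirical
type-I error ≈ 0.07–0.10 at nominal 0.05 in null simulations); the
t/F reference restores calibration (≈ 0.04–0.055) and is the standard
small-sample practice in quasi-likelihood count frameworks. The
genotype×age interaction is tested jointly on all interaction
coefficients (2 df for three age levels), reported as one p per gene.

All-zero genes within an analysis are flagged and excluded from that
analysis's BH denominator. Proteome intensities are rounded
half-to-even to integers before count-model fitting. BH adjustment is
the usual step-up with enforced monotonicity, applied within each
(modality, design) analysis separately. Independent filtering and
outlier replacement are intentionally not implemented.

## Permutation-based empirical FDR

Genotype labels are shuffled across samples — by default jointly
across ages, since the joint model's exchangeability unit is the
sample; a within-age blocked shuffle is available by flag because the
original procedure's blocking is not documented. The full fit
(normalization, dispersion, testing) is re-run per permutation.
Empirical FDR = mean null hits at the threshold / observed hits, with
the mean (not median) of null counts as the simplest consistent
estimator, division guarded when no observed hits exist. The default
1000 permutations can be reduced for testing; the package's own checks
use 200.

## Proteome preparation

Order of operations: group-completeness filter → isoform collapse →
imputation, matching the standard LFQ narrative. An "experimental
group" is a genotype×age cell with its replicate count taken from
metadata. Imputation operates on log2 intensities (raw input is
auto-transformed behind a flag); each sample's missing entries are
drawn from N(median_j − 1.8·sd_j, (0.3·sd_j)²). The 1.8-SD down-shift
is the established convention for detection-limit imputation; the
0.3-SD width is the companion convention (the width is not dictated by
the shift and is exposed as a parameter). With these defaults an
imputed value falls below the sample median with probability
Φ(1.8/0.3) ≈ 1 − 10⁻⁹. Samples with fewer than two observed values
cannot supply an SD and raise an error rather than guessing.

## Concordance

Quadrant classification uses strict signs; genes with an exactly-zero
fold-change in either modality are excluded from percentages and
counted in a warning. The concordance estimate is (D + 1)/2 where D is
Somers' delta of transcript LFC on protein LFC: over unordered pairs
with distinct predictor values, (concordant − discordant) / pairs,
ties in the response contributing half to each side (equivalently the
classical D_yx = (C − D)/(n₀ − T_x)). It is computed via the Kendall
tau-b identity in O(n log n) with the asymptotic normal p-value of the
associated tau test; a brute-force all-pairs oracle verifies the tie
convention in tests. Because a univariate monotone regression preserves
predictor order, this rank concordance is the model-free core of
"transcript fold-change ~ protein fold-change" concordance modeling.

## Clustering and eigengenes

Hierarchical clustering uses 1 − Pearson distance on depth-normalized,
log2(x+1)-transformed expression (the pseudo-count avoids log 0; a
flag disables the log for sensitivity checks), complete linkage, and
SciPy's deterministic merge order. Zero-variance genes are excluded.
The NMF rank survey runs multiplicative-update Frobenius NMF from
seeded random starts (default 30 runs per rank; 8–10 in tests), assigns
genes to their dominant basis component, averages co-assignments into a
consensus matrix, and scores each rank by the cophenetic correlation of
the consensus (residual = best reconstruction error as tie-break).
The chosen rank is applied as a manual cut of the dendrogram
(`maxclust`), with labels renumbered by first appearance. Cluster
trajectories are medians over member genes and replicates per
genotype×age cell, reported log2-transformed. Module eigengenes are
the first right singular vector of the gene-standardized submatrix,
unit norm, oriented so correlation with mean module expression is
non-negative (the standard eigengene convention), and correlated with
a 0/1 genotype indicator via Pearson with the t-distribution p-value.
The full WGCNA pipeline (soft-power adjacency, TOM, dynamic tree cut,
eigengene merging) is intentionally out of scope; `module_eigengene`
accepts any externally derived module membership.

## Enrichment and cross-species overlap

Over-representation uses the one-sided Fisher exact test on the 2×2
in-query × in-category table restricted to the declared background,
categories below 5 background members excluded, BH across tested
categories. Homology mapping keeps every (source, target) pair with
integer confidence score ≥ 5 — the inclusive boundary is the default
because the stated threshold "of 5" and the phrase "> 5" conflict in
the source conventions; a strict flag implements the alternative.
Multi-mapping is retained in full. The overlap statistic is the
upper-tail hypergeometric P(X ≥ k), computed as the survival function
at k − 1 in log space so that p-values near 10⁻⁶⁰ retain full relative
precision; this tail convention reproduces the three published
cross-species p-values to three significant figures, which fixes the
quantile convention empirically. Direction concordance counts a human
gene as concordant when at least one passing, Tau-significant homolog
changes in the same direction (a majority rule is available by flag).

## Modifier annotation

The amplifying/protective rule is a closed 2×2×2 table over
(DE direction, manipulation, outcome); all eight cells are defined and
flipping the direction with fixed evidence flips the call. Genes with
conflicting evidence across records are reported per-record with a
gene-level "conflicting" summary rather than a forced choice. DE
direction defaults to the age-adjusted joint model.

## Problem sizes and numerical choices

The package's own validation uses 2,000-gene simulations for
calibration and recovery, 300-gene spiked simulations with 200
permutations for the empirical-FDR property, and 45×12 planted-block
matrices for rank selection — sizes chosen so the full suite completes
in about a minute while leaving the statistical checks well-powered.
IRLS runs at most 60 iterations with a 10⁻⁹ step tolerance, linear
predictors clipped to ±30 to avoid overflow, and a 10⁻¹⁰ ridge on the
normal equations for singular-design safety (singular fits are flagged,
not fatal). Dispersion bounds are [10⁻⁸, 50]. Golden-section search
(50 iterations) is used instead of a derivative-based optimizer because
the Cox–Reid objective's derivative in α is expensive and the bracketed
search is robust to flat likelihoods at the lower bound.

## Known limitations

Dispersion estimates at n = 3 per cell remain noisy per gene without
cross-gene shrinkage, so per-gene power is below what moderated methods
achieve at equal calibration. The permutation null with 18 samples has
a limited number of distinct label assignments; empirical FDR estimates
below ~10⁻² are resolution-limited at the default permutation counts.
The NMF consensus survey is a heuristic: on weakly separated data the
cophenetic criterion can prefer a neighboring rank. Cross-species
conclusions inherit whatever ascertainment bias the homology table's
score distribution carries.
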