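# Methods

This note documents the models, conventions and numerical choices behind
`degatlas`, and what the synthetic-data generators do and do not emulate.

## Covariates from mixed metadata

Sample metadata mixes continuous variables (age, freezing time) and
categorical ones (sex, tissue, sequencing strategy). Before any design is
fit, missing values are imputed: continuous columns by the mean within the
sex stratum when a fully observed sex column exists (global mean
otherwise; a stratum with no observed value also falls back to the global
mean), categorical columns by a literal `"unknown"` level. A comparison
whose condition *is* one of the usual covariates (e.g. a sex contrast)
simply drops that variable from the covariate set rather than controlling
for its own condition.

To reduce the remaining variables into a few design covariates we use
correspondence analysis (CA) rather than PCA, because CA handles
indicator-coded categoricals and doubled continuous variables on an equal
footing. Continuous columns are min–max rescaled to z ∈ [−1, 1] and
"doubled" into ((1+z)/2, (1−z)/2); categoricals are one-hot coded. Both
codings give every variable constant row mass 1, so no variable dominates
by scale. CA is the SVD of the standardized residual matrix
S = D_r^{−1/2} (P − r c') D_c^{−1/2}; eigenvalues are squared singular
values, their sum is the total inertia χ²/n (an identity the tests verify
against a direct χ² computation), and the retained covariates are row
principal coordinates.

The number of retained components is the scree elbow, operationalised
reproducibly: the elbow is the scree point with maximum perpendicular
distance to the chord joining the first and last eigenvalues, and the
components *before* the elbow are retained (k = elbow index − 1, at least
1; linear screes and ≤2 eigenvalues give k = 1). Picking an elbow by eye
is common practice; fixing this rule makes builds deterministic, and k can
be overridden.

Constant continuous columns and single-level categoricals are dropped with
a warning rather than raised, because they are routine in subsetted
metadata; an empty covariate set yields an intercept-only design.

## Differential expression

Normalisation is median-of-ratios: the reference profile is the per-gene
geometric mean over genes positive in every sample; a sample's size factor
is the median ratio of its counts to the reference, rescaled to geometric
mean one. A `pseudo_reference` flag (geometric means over positive entries
only) rescues data where no gene is detected everywhere.

Each gene is fit by a negative-binomial (NB2) GLM with a log link and the
log size factors as offsets, via iteratively reweighted least squares
(weights μ/(1+αμ); the linear predictor is clipped at ±30 to keep all-zero
and perfectly separated genes finite — such genes are flagged rather than
fatal). The fitter is validated against an independent GLM implementation
(statsmodels) to 1e-6 and reduces to a Poisson fit as α → 0.

The condition effect is tested by a likelihood-ratio test: full design
(intercept + covariates + condition) vs reduced (intercept + covariates),
2Δl ~ χ²(1), BH across tested genes, DE at FDR < 0.05 by default with an
optional linear fold-change floor (`apply_cutoffs`). The reference
("down") level is the alphabetically first condition label, so log2
fold-changes are non-reference vs reference; swapping labels flips signs
and preserves p-values. Reported log2FC is the maximum-likelihood
coefficient — no shrinkage.

**Dispersion.** α is estimated gene-wise: a method-of-moments start, then
a bounded 1-D maximisation of the Cox–Reid-adjusted profile likelihood
(l(α) − ½ log det X'WX) on the log scale, floored at 1e-8 and capped
at 10. Two deliberate choices:

* *No empirical-Bayes moderation* (no trend fitting, no MAP shrinkage).
  The package's accuracy claims therefore rest on calibration properties —
  type-I error on null simulations within [0.03, 0.07] and high power at
  strong planted effects — not on value-level parity with any shrinkage
  scheme.
* *Estimation under the reduced design.* Estimating α with the condition
  in the model lets a chance group difference deflate the estimate for
  exactly the genes that then show a large LRT — a double dip that
  moderation normally absorbs and that, without it, inflated null type-I
  error to ≈0.08 in our simulations. Profiling the condition out restores
  calibration (≈0.04–0.06 across seeds) at the cost of some power for
  small effects (true effects inflate the dispersion); at the planted
  log2FC = 2, n = 10-per-group condition, power remains ~100%.

Because the χ²(1) reference is asymptotic, null p-values at ~12 samples
are close to, but not exactly, uniform (KS distance ≈ 0.02–0.04, mildly
conservative); the tests bound that distance rather than testing exact
uniformity.

There is no independent filtering or outlier (Cook's-distance-style)
handling: every gene with at least one nonzero count is tested. A
comparison fails only if more than half its nonzero genes are unfittable.

## Compendium assembly

Candidate comparisons pass uniform interpretability rules: ≥3 biological
replicates per group; no generic-ID conditions (a caller flag — sample-ID
groupings are not machine-detectable); same tissue in both groups; no
controlled-for categorical perfectly stratifying the groups; no
`NA`/`unknown` condition; time-series pairs must be reference-anchored or
adjacent (a pair skipping an existing intermediate level is out); in
studies with more than three candidate comparisons, treatment-vs-treatment
pairs are dropped; and after DE, comparisons with <5 or >10000 DEGs are
removed. Every exclusion is recorded with a machine-readable reason so
kept + excluded = input.

Comparisons are named `STUDY: Tissue.condA vs condB` with conditions in
alphabetical order ("vs" is used uniformly for machine parsability). Each
comparison is annotated by ranked-hypergeometric enrichment of its DEG
list — ranked by ascending FDR, ties by descending |log2FC| then gene id
(the tie-break is our choice; some tie-break must be fixed for
reproducible rankings) — against a pathway database filtered to 15–2000
genes and a TF-target database filtered to 15–5000 genes, within the
comparison's detected genes as background. All terms are stored with their
FDR regardless of significance. Summary cards keep the top 15 up / 15 down
DEGs and top 5 pathways / TFs.

## Enrichment engine

The overlap test is the upper-tail hypergeometric probability with an odds
ratio from the 2×2 table (Haldane +0.5 when any cell is zero). The ranked
variant takes the minimum tail probability over all prefixes of the
ranked query, reporting the minimising depth (smallest on ties) and the
overlap genes there. The minimum over depths is used *raw* — multiple
testing is handled across terms by BH, not across depths; this inherits
the behaviour of standard ranked-enrichment tools and slightly favours
terms with many plausible depths, which BH across terms does not correct.
Genes outside the background never influence the p-value.

Brown fusion uses the empirical variant: each channel's p-values are
transformed by w = −2 ln(ECDF), with a right-continuous ECDF so the
smallest value maps to 1/n (never log 0). The channel sums are referred to
a scaled chi-square with f = 2E²/Var, scale Var/(2E), E = 2m, and Var the
empirical variance of the sums (per-channel variances plus twice the
covariances). The empirical variant is preferred over the polynomial
covariance approximation because the fused channels here always come with
joint samples. One channel is the identity; independent uniform channels
recover Fisher's method (verified by KS distance in the tests).

## Queries

Input modes: `full` (genes + p-values + coefficients), `ordered` (ranked
genes only: p_i = 0.049·i/n, Pearson disabled, Spearman uses the negated
rank as a coefficient surrogate — only its ordering matters), `unordered`
(all p = 0.049, both correlations disabled). 0.049 sits just under the
conventional 0.05 mark so synthesised values count as significant without
fabricating strong evidence. Duplicate symbols collapse by minimum
p-value by default (first-occurrence available); matching is
case-sensitive with an optional upper-casing flag for human symbols, and
none for Ensembl-style identifiers.

The background is the user's list if supplied, else the union of detected
genes across the compendium; query genes absent from the background are
appended with a warning.

`deet_enrich` runs four channels: (1) DEG overlap — ranked hypergeometric
of the query against every comparison's DEG set; (2, 3) pathway / TF
overlap — hypergeometric overlap of the user's significant terms with each
comparison's significant terms, over the size-filtered term universe (the
universe choice is ours; some finite universe is required); (4)
correlations — Spearman (and Pearson in full mode) between user
coefficients and stored log2 fold-changes on shared DEGs, computed only
within comparisons already enriched at the gene level, missing when fewer
than 3 genes overlap or a vector is constant. Each channel is
BH-corrected separately at α = 0.05 (configurable). `input_as_reference`
reverses the roles: the user list becomes a one-set database and each
comparison's FDR-ranked DEG list is the query, so stored significance
profiles drive the enrichment.

`overlap_stats` reports compendium-specific, study-specific and
intersecting DEG counts; its "genes captured" percentage is the
intersecting count as a fraction of the study-specific count, matching the
printed convention of the benchmark tables it mirrors.

## Compendium analytics

Pairwise comparison similarity is the squared Pearson correlation of two
comparisons' FDR vectors over genes DE in at least one of the pair and
detected in both (missing below 3 co-usable genes). Clustering embeds the
rows of |r| (= √r²; clustering on r² is available by flag — the two are
monotone for a similarity matrix but give different Euclidean geometries)
with Ward's criterion on Euclidean distances (Ward.D2), cut at a height
(default 30, data-scale dependent) or into a requested number of clusters.
Missing similarities are imputed as 0 — the most conservative choice.
Median within-cluster DEG sharing uses ordered pairs, |DEG_i ∩ DEG_j| /
|DEG_i|. Cluster annotation fuses member comparisons' per-gene FDR vectors
with the empirical Brown method (a gene missing from a member contributes
p = 1) and feeds the fused ranking to the enrichment engine.

The DE prior is frequency-based: de_frequency(g) = #comparisons where g
is DE / #comparisons where g is detected, densely ranked with
lexicographic tie-breaks. Two priors are compared by hypergeometric
overlap of their top-q sets at cumulative increments (default 1%), BH
across increments; the q = 1 increment is degenerate and reported with a
missing odds ratio. (The multifunctionality-optimised prior from the
microarray literature is a different statistic; an external prior can be
supplied as a plain ranked table.)

## Feature extraction

The fold-change matrix keeps genes detected in ≥70% of comparisons
(inclusive); undetected cells are 0-filled behind an explicit mask. The
70% floor plus zero-fill is the concrete resolution of the sparse-gene
over-prediction problem: a gene observed in few studies can spuriously
"predict" responses that co-occur in those studies.

The elastic net uses mixing parameter 0.5 and picks its penalty by
10-fold cross-validation with the 1-SE rule (largest penalty within one
standard error of the minimum CV error), seeded; both are configurable.
Families: gaussian (continuous response), binomial (two classes),
multinomial (reported per-gene coefficient = max |coefficient| across
classes). The paired univariate statistics are Spearman's rho, the
Wilcoxon rank-sum and one-way ANOVA respectively, BH across genes.
Predictor importance regresses every gene on all others and column-sums
the absolute coefficients; the O(genes²) cost is bounded by a seeded
uniform subsample (default cap 2000 genes).

## Synthetic data: what it does and does not emulate

`simulate_counts` draws log-normal baseline means (median ≈ 100 counts,
log-sd 1.2), NB noise at a chosen dispersion (default 0.1, a mid-range
bulk RNA-seq value), and plants Normal(0, lfc_scale) log2 fold-changes
(magnitudes floored at 0.25 so planted truth is well defined) on a random
de_fraction of genes; an optional batch shifts a third of the genes,
balanced or confounded. Defaults are 2000 genes and 6 samples per group —
a small but realistically shaped two-group experiment.

`simulate_compendium` plants block structure directly at the DEG-table
level: each block owns a shared DEG core covering a chosen fraction of
every member's DEGs, fold-changes on the core are correlated within a
block, FDRs for DEGs are Beta(1, 50) truncated below 0.05 and Uniform
(0.05, 1] otherwise — shaped like thresholded DE output so the 0.05
cutoff separates exactly. The first comparison doubles as a planted query
match. Defaults (12 comparisons, 2 blocks, 1500 genes, 120 DEGs, 90%
detection) keep every planted-recovery check well inside a desk-scale
compute budget.

What passing these tests shows: the machinery (tests, fusion, ranking,
clustering, regression) behaves correctly on data with known structure.
What it does not show: robustness to the messiness of real compendia —
inconsistent metadata vocabularies, correlated technical artefacts across
studies, heavy-tailed dispersions, unbalanced designs — and no claim of
numeric parity with any specific published compendium is made at this
scale.

## Problem sizes and determinism

Simulation-based checks run at 2000-gene null DE, 12–14-comparison
compendia, 200×40 regression designs and 100–1000-instance oracle sweeps;
these sizes make every property detectable while keeping a full run in
minutes on a single CPU. All generators and CV splits are seeded;
rebuilding a compendium from the same inputs is byte-identical (fixed
iteration order, 17-significant-digit float serialisation).
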