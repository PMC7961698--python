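# Methods

This note documents the models, numerical choices and limitations behind
`crcprograms`, in the order the pipeline runs them.

## Expression model and preprocessing

Counts are normalized per cell to counts-per-million against the library
total *at input*, before any gene filtering, and transformed as
E = log2(CPM/10 + 1). The per-gene aggregate is Ea = log2(mean_cells(E) + 1)
with genes below `min_ea` excluded; the exclusion is strict (`< min_ea`)
and the boundary gene is retained. Note that because per-cell CPM sums to
10^6, only a few dozen genes in any dataset can reach mean(E) large enough
for Ea ≥ 3.5; the cutoff is therefore exposed as a parameter, and the
synthetic-scale configuration (`synthetic_pipeline_config`) uses
`min_ea = 2.0`, which retains intermediately-to-highly expressed genes at
the simulated library scale (~10^4 counts over 2000 genes).

QC thresholds are strict inequalities exactly as configured
(reads > 100,000; detected genes > 1000; mitochondrial fraction < 0.15).
The per-patient top-read rule removes `floor(q·n)` cells per patient
(q = 0.05), ranking by reads with a stable sort so ties resolve in input
cell order. Mitochondrial content is taken from per-cell metadata; when
derived from gene symbols, the standard human "MT-" prefix convention is
assumed. An optional PCA-outlier rule (cells whose distance from the
centroid in top-10 PC space exceeds the mean by `pca_outlier_sd` SDs) is
off by default: cells are not dropped silently on an under-specified
criterion.

Per-patient mean-centering subtracts, for each gene, the patient mean;
it is idempotent and leaves signed residuals with zero mean per patient
(verified to 1e-9). Differential expression between patients is one-vs-rest
two-sided Wilcoxon rank-sum per gene with Benjamini–Hochberg adjustment
within each contrast; markers must pass adjusted p < 0.05 and log
fold-change > 0.25 (up-regulated in the patient), ranked by adjusted p then
|log fold-change|.

## NNMF and factor curation

The clipped centered matrix (negatives set to zero) is factorized
genes x cells as X ~ W·H with Frobenius multiplicative updates. MU was
chosen over projected alternating least squares because its objective is
non-increasing at every iteration, which makes the "reconstruction error
never rises within a fit" contract testable exactly; convergence is
declared when the per-iteration error drop falls below `tol = 1e-4`
relative to ||X||, with `max_iter = 500` (300 in the synthetic-scale
configuration). Ten restarts from seeded uniform random initializations
(spawned from one seed sequence) are fitted and the lowest final error
wins, so a fit is a pure function of (matrix, k, seed). sklearn's NMF
serves as an independent cross-check in the test suite, never as the
implementation.

Patient-specific factors are detected from per-patient distributions of the
factor's cell scores: histograms on 50 shared equal-width bins spanning the
pooled score range, pairwise overlap = sum of bin-wise minima of the two
normalized histograms, a patient failing when its median overlap with the
others is < 0.5. The default excludes a factor when ≥ 5 patients fail — the
rule as printed — and `min_patients=1` gives the stricter "any dominated
patient excludes" variant aimed directly at single-patient factors; both
are exercised in tests. With finite cells per patient the empirical overlap
of identical distributions is below 1 (sampling noise across 50 bins), so
the 0.5 threshold should be read as generous; at 200 cells/patient
genuinely shared factors sit well above it.

Signatures are the top 200 loading genes per retained factor, ranked by
loading with ties broken by gene identifier (stable under input gene
order). Signatures whose non-zero-loading prefix is shorter than requested
are flagged degenerate rather than truncated.

## Scoring, meta-signatures and assignment

Scores are computed on the uncentered E values: raw score = mean E over the
signature genes present (≥ 50% must be present), background = mean E over
control genes drawn per signature gene from the same aggregate-expression
bin (25 equal-occupancy rank bins, 100 controls per gene, drawn without
replacement within a bin when possible), corrected = raw − background. A
signature drawn at random from its own bins therefore scores ~0, and a
constant matrix scores exactly 0. Scoring on centered values is available
by passing the centered matrix.

Meta-signatures merge signatures whose corrected score vectors cluster
together: complete linkage on 1 − Pearson r, tree cut at 1 − 0.6. The
merged gene list is the union ordered by best per-factor rank. Because
control genes are drawn from expression bins shared with other programs'
genes, corrected scores of co-activated programs are somewhat
de-correlated relative to their activation indicators; strongly coupled
programs (for example cell cycle and OXPHOS in a TA-dominated regime)
still merge at the default cut.

A type program is active in a cell when its corrected score exceeds the
across-cells mean by more than one population SD (ddof = 0 — fixed for
reproducibility; the ddof choice vanishes at cohort scale). The threshold
applies to corrected scores, since assignment consumes corrected scores
throughout. Cells take the argmax over active type programs, or
`unassigned`; a constant score column activates nobody. State contrasts
between assigned types use the two-tailed Mann–Whitney U with medians and
quartiles reported; an all-tied comparison reports p = 1 explicitly.

## Bulk stratification and survival

Bulk samples are scored as mean log2 expression over present signature
genes (≥ 50% presence required; missingness recorded). The six-cluster
stratification performs five fixed binary splits, each a complete-linkage
hierarchical clustering cut at two branches: (1) {OXPHOS_1, G1/S, G2/M,
stem} separate the high branch {cl2, cl3}; (2) {hypoxia/glycolysis_1,
TNFα_2} split cl3 (high) from cl2; (3) {fatty acid, TNFα_1} split cl1
(high) from {cl4, cl5, cl6}; (4) {stem, TA} split by correlation distance,
the stem-low branch becoming cl6; (5) {G1/S, G2/M, OXPHOS_1} split cl4
(medium) from cl5 (low). A k = 2 cut is used at every split (cut heights
are not uniquely determined by the verbal description); "medium" vs "low"
is decided by ranking branch means. With two features, correlation distance
reduces to the sign of (stem − TA) after centering, which is exactly the
stem-low/stem-high dichotomy wanted at step 4.

Kaplan–Meier curves, the multivariate log-rank test and Cox
proportional-hazards fits come from lifelines; merged contrasts (e.g.
cl4+cl5+cl6 vs cl1+cl2+cl3) are expressed through a group map. Nested Cox
models are compared by 2·Δ(partial log-likelihood) against chi-square with
df = number of added cluster indicator terms; constant covariates are
dropped with a warning, and non-convergence raises. The survival
significance threshold defaults to p < 0.1, configurable.

## Limiting dilution

The single-hit Poisson model sets P(negative well) = exp(−f·d). The
log-likelihood is maximized on the log-f scale by bounded Brent search
(tolerance 1e-12 on log f); a single-dose assay has the closed form
f = −ln(1 − r/n)/d, which the optimizer matches to 1e-8 relative. 95%
confidence limits invert the likelihood-ratio statistic at
chi-square(1) = 3.841 by bracketed root finding; LR intervals remain
usable at the small well counts of these assays, and a Wald interval on
log f is provided for cross-checking. Boundary cases are flagged: all
wells negative gives f̂ = 0 with the closed-form one-sided upper limit
chi2/(2·Σ n·d); all wells positive pins f̂ at the upper edge with a
one-sided lower limit. The P(negative) = (1−f)^d binomial variant differs
negligibly at f ≪ 1 and is not implemented. Between-condition comparison
is a likelihood-ratio test of one shared frequency versus two (chi-square,
1 df); under the in-vivo five-dose layout with 3–6 animals per dose its
measured power for a 1/250 vs 1/2000 contrast is ~0.83. Ratios to a bulk
estimate propagate uncertainty on the log scale from the CI half-widths.

## Synthetic data: what it emulates, what it does not

The spheroid generator draws counts gene-by-cell from a negative binomial
(dispersion θ = 5; Poisson as θ → ∞) around
lib_j · 2^(baseline_i + offset_pi + Σ active program effects), with
per-gene baselines N(2, 1) on log2, per-patient per-gene offsets N(0, 0.8)
reproducing the dominant patient-of-origin clustering of real cohorts,
log-normal library-size factors (σ = 0.3), and read totals ≈ 60 reads per
count so that study-scale QC thresholds are meaningful. The default cohort
is 8 patients x 200 cells and 2000 genes with seven disjoint planted
programs of 150 genes each at a +2.0 log2 effect: four cell types (stem
25%, TA 30%, Paneth 15%, Tdiff 30%) and three states activated per cell by
a Bernoulli conditioned on type (TA high in cell cycle and OXPHOS, Tdiff
high in hypoxia/glycolysis, stem intermediate in OXPHOS — the overlap
structure reported for these compartments). All randomness flows through
one seeded generator per call.

Program recovery is measured as the top-gene Jaccard between a planted
gene set and the best meta-signature, where a meta-signature matches
either through its union prefix or through any member factor signature
(both truncated to the planted size): merging two genuinely coupled
programs into one meta-signature is desired behavior and must not be
scored as a recovery failure.

The bulk generator plants six cluster archetypes over nine signatures with
levels chosen to encode the published cluster profiles; cl4's "medium"
level is 0.4x the high shift because an exact midpoint would be
equidistant between the high archetype and the low clusters at the first
split. Survival is exponential with cluster-specific hazard and
independent exponential censoring. The dilution generator draws wells
i.i.d. from the single-hit model.

Not simulated: ambient RNA, doublets, batch chemistry, dropout beyond NB
sparsity, spatial structure, non-proportional hazards, heterogeneous
(multi-hit) dilution responses. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
assumptions, not robustness to these real-data artifacts.

## Problem sizes and determinism

The end-to-end validation runs the default 8 x 200-cell cohort with k = 10
and 10 restarts; the dilution calibration uses 1000 simulated assays; the
stratification checks use 90 noise-free and 360 noisy samples and 100
survival replicates. These sizes give stable Monte-Carlo estimates while
keeping a full run in the minutes range on one core. Every stochastic
component is seeded; identical seeds give bit-identical matrices, fits and
manifests (file writes are atomic, temp-then-rename).

## Known limitations

- The printed aggregate-expression formula caps how many genes can pass
  Ea ≥ 3.5 (see above); cross-dataset use requires choosing `min_ea` for
  the library scale at hand.
- The patient-overlap factor filter is histogram-based; with very few
  cells per patient the finite-sample overlap of identical distributions
  drifts below 1 and the rule becomes conservative.
- The progressive splitter assumes the named signatures are present and
  informative; it does not re-derive the split order from data.
- Cox model comparison uses lifelines' tie handling (Efron); with heavily
  tied times the null partial likelihood from other conventions differs
  slightly.
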