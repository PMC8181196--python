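# Methods

This note documents the statistical procedures implemented in `lnc6`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Subtype discovery

Samples are clustered by agglomerative hierarchical clustering on the
`n_top = 1000` most variable genes (sample SD, ties broken by gene ID).
The default distance is correlation distance, `d(i, j) = 1 − r(x_i, x_j)`
over the selected genes, the conventional similarity for expression
subtyping because it ignores per-sample scale and offset. Genes should be
median-centered before clustering (the end-to-end pipeline and CLI do this
by default): on raw log2 data the shared per-gene baselines dominate every
pairwise profile correlation and compress the dynamic range of the
distances, masking subtype structure.

The default linkage is Ward's criterion. Average linkage — the other
common choice, also available — proved fragile here: a single mildly
outlying sample is often kept aside until the very last merges, so cutting
the tree at K produces a singleton cluster and silently merges two true
subtypes. Ward's variance criterion absorbs such samples into their
nearest cluster. Cluster labels are renumbered 1..K by decreasing size
(ties: lexicographically smallest member sample ID), so labels are stable
across sample orderings and runs.

K defaults to 6 and is never auto-selected; `evaluate_k` reports the mean
silhouette width over a K range (computed on the same distance used for
clustering) as a diagnostic.

## Signatures

For each subtype, per-gene pooled-variance (Student) two-sample t-tests
contrast the subtype against all remaining samples; degrees of freedom are
`n − 2`, p-values two-sided. Pooled variance (rather than Welch) matches
the compound covariate tradition in which the t-statistics double as
classifier weights; Welch would decouple the weight from the score-variance
model. The log ratio is the difference of group means on the log2 scale
(the log2 fold change, since the data are log-scale).

A signature keeps genes with `p < 0.001` and log ratio > 0 — subtype
signatures here are up-regulation signatures, matching the block-up
structure the generator plants — ranked by descending log ratio with
lexicographic gene-ID tie-break, truncated to 200 genes. Ranking by
absolute log ratio without the sign gate is available (`rank_by="abs"`).
No multiple-testing correction is applied at this stage: the threshold is
an intentional raw per-gene gate, and the test suite verifies that the
t-test's null false-positive fraction matches its nominal level, so the
expected null contamination of a signature is `α/2 × n_genes`.

Degenerate genes (zero pooled variance) get `t = 0, p = 1` when the group
means agree and `t = ±inf, p = 0` otherwise.

## Bayesian compound covariate predictor

Each subtype has an independent binary one-vs-rest model. On the z-scored
training matrix (per-gene mean 0, sample SD 1), the compound covariate of a
sample is the weighted sum of its signature-gene values, weights = the
signature's t-statistics. The training scores' class means and pooled
within-class SD define two shared-variance Gaussians; the posterior
probability of subtype membership follows from Bayes' rule with prior 0.5.
The implementation evaluates the posterior through its logistic form
(log-likelihood ratio plus log-prior odds), which is exact and stable for
arbitrarily extreme scores.

Choices worth stating:

* **Shared within-class variance.** The pooled SD keeps the posterior a
  monotone function of the score; per-class variances would make it
  non-monotone in the tails for no benefit at these sample sizes.
* **Priors of 0.5, not empirical frequencies.** With K = 6 the "rest"
  class outnumbers the subtype roughly 5:1; empirical priors would push
  every posterior toward 0 and make the argmax assignment dominated by the
  majority class. Empirical priors remain available per model.
* **No renormalization across subtypes.** Each posterior is a standalone
  one-vs-rest probability, usable on its own as a predictor (e.g.
  correlating one subtype's probability with drug response); the hard
  label is the argmax, ties resolved to the smallest subtype index.
* **Cross-cohort transfer = per-cohort z-scoring.** A model trained on one
  platform is applied to another by z-scoring the test cohort per gene
  within itself. This absorbs additive per-gene batch/platform offsets
  exactly (the generator's batch model) and approximately handles scale
  differences. Genes missing from a test cohort contribute 0 — their
  z-scored expectation — with a hard error when fewer than 50% of a
  model's genes are present.

### Cross-validation

`loocv_auc` is the validation of record. For every held-out sample the
entire derivation — one-vs-rest t-tests, the p/log-ratio gates, ranking,
truncation, z-scoring, weights, Gaussian score parameters — is recomputed
on the remaining n−1 samples; the held-out sample is standardized with the
fold's per-gene mean/SD (a one-sample "cohort" cannot standardize itself)
and scored. Per-subtype performance is the one-vs-rest AUROC of the
held-out posteriors against cluster-membership truth, computed by the
Wilcoxon mid-rank formula. Internally the fold statistics are obtained by
subtracting the held-out sample's contribution from full-cohort moment
sums, which is algebraically identical to recomputing from scratch (the
test suite asserts equality to ~1e-9 against a naive rebuild) and keeps
LOOCV at ~3 s for n = 300 x 4000 genes. Resubstitution AUC is available
separately and reported as such.

## Survival analysis

Kaplan–Meier product-limit estimation and the K-sample log-rank test are
implemented directly from their formulas: at each pooled event time the
observed events per group are compared with expectation proportional to
at-risk counts, with hypergeometric variance `d(n−d)/(n−1) ×
(diag(n_j)n − n_j n_j')/n²`; the statistic is the quadratic form over K−1
groups (pseudo-inverse for safety), chi-square with K−1 df. Ties: events
at a tied time are processed together; censored observations at the same
time remain at risk for it. Both estimators are cross-checked against
lifelines on random data in the test suite, and the log-rank's type-I
error is verified to sit near its nominal 5% over 2000 null simulations.

Pairwise subtype comparisons are adjusted by Benjamini–Hochberg over the
pair family (Bonferroni via flag). Endpoints (overall vs recurrence-free
survival) are record filters, not separate code paths; the within-subtype
treatment comparison expects the caller to have pre-filtered the analysis
population (e.g. by stage).

## Associations

* **Cross-tabulation**: contingency counts of two labelings over their
  shared samples — the data behind a chord diagram; rendering is out of
  scope.
* **Drug screen**: per-drug Spearman correlation (mid-ranks; two-sided p
  by t approximation for n ≥ 10 and exact permutation enumeration below)
  between dose-response AUC and a subtype's predicted probability over
  cell lines; missing AUCs dropped pairwise, constant-rank drugs reported
  as missing. `concordant_hits` requires `p < 0.05` with the specified
  correlation sign in *every* independent panel — deliberately a
  per-dataset gate, not a meta-analysis.
* **Pre-ranked GSEA**: genes ordered by a ranking metric (for responder
  stratification: the signature module's t-statistic of responders vs
  non-responders); hits advance the running sum proportionally to
  |metric|^w (w = 1 default; w = 0 gives the classical KS statistic),
  misses retreat uniformly; ES is the signed maximum deviation. The
  p-value permutes gene-set membership over genes — the standard
  pre-ranked fallback when the phenotype groups are too small to permute —
  with the add-one convention, so `p ≥ 1/(n_permutations + 1)`. NES
  divides ES by the mean |permuted ES| of the same sign.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* the pipeline assumes, not any
real cohort. Expression is Gaussian on the log2 scale around per-gene
baselines N(8, 1): each of K = 6 subtypes (uniform proportions, n = 300)
up-regulates its own disjoint block of 500 marker genes by `effect_size`
(default 4.0) log2 units against within-subtype noise SD 1.0, in both a
4000-gene lncRNA and a 4000-gene mRNA space sharing the sample axis. Test
cohorts add one N(0, batch_shift_sd²) offset per gene, shared by all
samples — a pure additive platform effect. Survival is exponential per
subtype (defaults order the subtypes from poor to good prognosis, with a
treatment hazard ratio of 0.4 in one subtype only and 1.0 elsewhere),
censored by an independent exponential truncated at 120 months; treatment
arms are Bernoulli(0.5) independent of subtype. Drug panels couple 3 of 20
drugs' AUC linearly (slope −6, noise SD 1) to a provided membership
probability across 40 cell lines.

Not emulated: count-level sequencing noise and normalization artifacts,
correlated gene modules beyond the planted blocks, down-regulated markers,
overlapping/mosaic subtypes, non-proportional hazards, informative
censoring, multiplicative batch effects, and probe-mapping loss between
platforms. Passing tests therefore demonstrate that the implementation is
correct under its stated model — clean additive signals and additive batch
shifts — not that the pipeline would reach the same operating
characteristics on real microarray/RNA-seq cohorts, where effect sizes are
smaller and structure is messier.

## Numerical conventions and degenerate inputs

Sample SD uses the n−1 denominator throughout. Z-scoring zeroes and flags
constant genes. All ordering tie-breaks are lexicographic by identifier
(variable-gene filter, signature ranks, GSEA ranking, cluster
renumbering), making every result invariant to input row/column order.
Every source of randomness is an explicit integer seed; writers format
numerics to 6 decimals, so identical configs and seeds produce
byte-identical artifacts (hashes recorded in the run manifest). Empty
signatures warn rather than fail; in LOOCV a fold with an empty signature
leaves that sample's posterior undefined and it ranks last. Problem sizes
used by the test suite and the validation script (10–20 seeds, n = 300,
4000 genes per space, 2000 null survival simulations) were chosen as the
smallest scales at which the verified properties are stable.

## Known limitations

The BCCP variant here (t-statistic weights, pooled shared-variance
Gaussians, 0.5 priors) is one concrete member of the compound-covariate
family; it is validated against its own closed form and brute-force
oracles, not asserted to be bit-identical to any historical software.
Clustering quality — and everything downstream of the discovered labels —
depends on the variable-gene filter and linkage; the defaults are
justified above but remain configuration, not claims. Real-data
normalization (CEL/FASTQ processing, probe-to-gene mapping, alias
resolution) is out of scope: gene matching is exact string identity.
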