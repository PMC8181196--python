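# lnc6

Molecular subtyping of gastric tumors from long non-coding RNA (lncRNA)
expression, as a tested, reusable pipeline: unsupervised subtype discovery,
subtype-specific gene signatures, a Bayesian compound covariate predictor
(BCCP) that assigns per-sample subtype probabilities across cohorts and
platforms, and the downstream association analyses that make such a
stratification clinically interesting — prognosis, within-subtype treatment
benefit, concordance with alternative subtype systems, drug-sensitivity
screening, and gene-set enrichment.

The package is aimed at computational-biology practitioners who want the
full chain runnable and testable without any external cohort: a synthetic
data module generates expression cohorts with planted subtypes, censored
survival with subtype- and treatment-dependent hazards, and cell-line drug
panels coupled to a subtype's membership score, so every stage can be
verified against ground truth.

## The method

**Discovery.** Tumors are clustered on the `n_top` most variable lncRNAs
(correlation distance `1 − r` between sample profiles, Ward linkage by
default, genes median-centered first) and the tree is cut into K = 6
subtypes.

**Signatures.** Each subtype *k* is contrasted against the rest by per-gene
pooled-variance two-sample t-tests. Genes with two-sided `p < 0.001` and a
positive log ratio (difference of log2 group means) are ranked by
descending log ratio; the top 200 form the subtype's signature.

**Classification.** The compound covariate of sample *x* for subtype *k* is

    s_k(x) = Σ_g  t_{kg} · x_g        (g over signature genes, x z-scored)

with weights equal to the training t-statistics. Training scores are
modeled as two Gaussians with class means μ_in, μ_out and shared pooled SD
σ; the Bayesian probability score of a new sample is

    P(k | s) = π φ(s; μ_in, σ) / [π φ(s; μ_in, σ) + (1−π) φ(s; μ_out, σ)]

with prior π = 0.5. The K one-vs-rest posteriors are not renormalized;
the hard assignment is their argmax. New cohorts are z-scored per gene
within themselves before scoring, which absorbs additive platform/batch
shifts. Validation is leave-one-out cross-validation with full re-derivation
of signatures and models inside every fold, summarized as per-subtype
one-vs-rest AUROC.

**Associations.** Kaplan–Meier curves and K-sample log-rank tests
(Benjamini–Hochberg-adjusted pairwise comparisons) for subtype prognosis
and within-subtype treated-vs-untreated contrasts; contingency tables
against alternative subtype labelings; per-drug Spearman correlation of
dose-response AUC with a subtype's predicted probability across cell
lines, with a hit filter requiring a significant correlation of the same
sign in every independent panel; and pre-ranked GSEA (weighted KS running
sum, gene-label permutation p-values).

## Worked example

```python
import numpy as np
from lnc6 import bccp, discovery, io, signature, synthetic

cfg = synthetic.CohortConfig(seed=1)          # n=300 tumors, K=6, 4000 genes/space
lnc, mrna, true_labels = synthetic.generate_training_cohort(cfg)

lnc_centered = io.median_center_genes(lnc)
genes = discovery.select_variable_genes(lnc_centered, n_top=1000)
clusters = discovery.hierarchical_cluster(lnc_centered, genes, k=6)
print("cluster sizes:", np.bincount(clusters.labels)[1:])

sigs = signature.build_all_signatures(mrna, clusters.labels, p_threshold=0.001, max_genes=200)
print("signature sizes:", [len(s) for s in sigs])

models = bccp.train_multiclass(io.zscore_genes(mrna), clusters.labels, sigs)
auc = bccp.loocv_auc(mrna, clusters.labels)
print(auc.to_string(index=False))
```

prints

```
cluster sizes: [56 53 49 49 48 45]
signature sizes: [200, 200, 200, 200, 200, 200]
 subtype  auc
       1  1.0
       2  1.0
       3  1.0
       4  1.0
       5  1.0
       6  1.0
```

The six clusters recover the six planted subtypes; with ≥500 planted
markers per subtype every signature saturates its 200-gene budget; and the
cross-validated posterior separates each subtype from the rest perfectly at
the default 4-sigma marker effect (an AUROC of 1.0 means every held-out
in-subtype sample outranks every out-of-subtype sample).

The same chain is available from the shell:

```bash
lnc6 run-all --seed 1 --out-dir demo_run        # full pipeline + JSON manifest
lnc6 discover --expression lnc.tsv --k 6 --out labels.csv
lnc6 signature --expression mrna.tsv --labels labels.csv --out sig.gmt --stats sig_stats.csv
```

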