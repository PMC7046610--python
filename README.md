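# emtsig

Epithelial-mesenchymal transition (EMT) subtype analysis for bulk
expression cohorts — built for head and neck squamous cell carcinoma
(HNSCC) but applicable to any log-scale gene-by-sample matrix with the
four canonical EMT markers.

The package is for computational biologists who want to reproduce, stress
or extend this analysis pattern end to end without access to the original
cohorts: every stage can be exercised on synthetic multi-cohort data with
planted truth.

## What it does

1. **Signature discovery** — Pearson-correlate every gene against the EMT
   anchors CDH1 (epithelial) and VIM / CDH2 / FN1 (mesenchymal); select
   genes with |r| ≥ r_min and BH-adjusted q ≤ q_max for at least one
   anchor; orient each gene epithelial or mesenchymal by its strongest
   anchor correlation.
2. **Subgrouping** — two-way hierarchical clustering (1 − Pearson
   correlation distance, complete linkage) on the signature genes, cut at
   k = 2; the cluster with the higher mesenchymal-minus-epithelial z-score
   contrast is the Mes subgroup.
3. **Cross-cohort classification** — a Bayesian compound covariate
   predictor (BCCP). With t_i the two-sample t statistic of gene i
   (Mes − Epi) on standardized training values, the compound covariate is
   c_j = Σ_i t_i x̃_ij and

       P(Mes | c) = π_M φ(c; μ_M, σ) / [π_M φ(c; μ_M, σ) + π_E φ(c; μ_E, σ)]

   with class-conditional Gaussians fitted on training covariates.
   Training robustness is the leave-one-out cross-validation
   misclassification rate; independent cohorts are harmonized (common
   genes, per-cohort gene-wise z-scores) before prediction.
4. **Immune scoring** — per-sample INFG, CYT, TIS, IIS and IS scores plus
   checkpoint-gene (PDCD1, CD274, CTLA4) summaries.
5. **Survival & association statistics** — Kaplan-Meier / log-rank, Cox
   proportional hazards (univariate and multivariate), rank-sum score
   comparisons, Fisher / chi-square contingency tests and local gene-set
   enrichment.
6. **Synthetic cohorts** — a generator planting the latent Epi/Mes state,
   anchor-correlated signature blocks, immune elevation in Mes,
   proportional-hazards survival and cross-platform distortions, so every
   claim above is testable against known truth.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from emtsig import (
    SyntheticCohortSpec, generate_multi_cohort, harmonize_cohorts,
    compute_marker_correlations, select_signature_genes,
    hierarchical_cluster_two_way, assign_subgroup_labels,
    fit_bccp, loocv_misclassification, predict_bccp, logrank_test,
)

spec = SyntheticCohortSpec(seed=1, n_samples=300, n_noise_genes=1000)
train, *tests = generate_multi_cohort(spec, n_test_cohorts=3)

table = compute_marker_correlations(train.expression)
signature = select_signature_genes(table, r_min=0.5, q_max=0.05)
print(len(signature), "signature genes")

clusters = hierarchical_cluster_two_way(train.expression, signature)
labels = assign_subgroup_labels(clusters, train.expression, signature)
model = fit_bccp(train.expression, labels, signature)
print("LOOCV misclassification:", loocv_misclassification(train.expression, labels, signature))

harmonized = harmonize_cohorts([train.expression] + [t.expression for t in tests])
for cohort, hexpr in zip(tests, harmonized[1:]):
    pred = predict_bccp(model, hexpr)
    acc = (pred.labels == cohort.true_labels).mean()
    lr = logrank_test(cohort.clinical, pred)
    print(f"{cohort.expression.name}: accuracy {acc:.3f}, log-rank p {lr.p:.3g}")
```

Output:

```
38 signature genes
LOOCV misclassification: 0.0
test1: accuracy 1.000, log-rank p 0.00639
test2: accuracy 1.000, log-rank p 0.000675
test3: accuracy 1.000, log-rank p 0.0658
```

38 of the 40 planted signature genes clear the selection thresholds (the
planted anchor correlation sits exactly at r_min = 0.5 here, so a couple
of genes fall just short by sampling error — see `docs/methods.md`); the
classifier still transfers perfectly to the platform-shifted cohorts, and
the predicted subgroups show the planted survival disadvantage of the
mesenchymal group (true hazard ratio 0.65 for Epi) at the power n = 300
per cohort affords — significant in two of three test cohorts.

Or from the shell:

```bash
emtsig demo --outdir demo_out --seed 17     # synthetic end-to-end run
emtsig run --config analysis.yaml           # your own cohorts
emtsig discover --expression expr.tsv       # single stages: discover /
emtsig classify / score / stats             # classify / score / stats
```

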