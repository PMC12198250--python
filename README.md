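# egfrsig

Tumors with high EGFR signaling tend to respond poorly to immune
checkpoint inhibitors (ICIs), but single biomarkers such as EGFR mutation
status explain the effect only partially. `egfrsig` implements a
pan-cancer analysis pipeline that derives an **EGFR-related gene
signature** from many single-cell RNA-seq cohorts, validates it against
genome-wide CRISPR immune screens, uses it to predict ICI response, and
condenses it into a hub-gene risk score for survival stratification. It
is aimed at computational biologists who want each stage of such a
signature study as a tested, reusable, scriptable component — and who
want to verify the statistics against planted ground truth before
trusting them on real cohorts.

## The method

**Signature derivation.** In each single-cell dataset, per-cell EGFR
activity is summarized by a single-sample enrichment score ES (an
ssGSEA-style weighted Kolmogorov–Smirnov walk over the within-cell
expression ranks). Within malignant cells, a gene *g* enters

- *Gx* if Spearman ρ(*g*, ES) > 0.2 at BH-FDR < 0.05,
- *Gy* if its malignant-versus-rest mean log₂ difference ≥ 0.5 at
  Wilcoxon BH-FDR < 0.05,

and *Gn = Gx ∩ Gy* is the dataset's contribution. Across datasets the
retained coefficients are combined per gene by geometric mean, and genes
with geometric-mean ρ > 0.4 form the merged signature.

**CRISPR validation.** Knockout log-fold changes are z-normalized per
screen, genes are ranked ascending by mean z across screens, the lowest
6% of ranks are flagged as immune-resistance genes, and the flagged
proportion inside a signature measures its enrichment for such genes.

**Response and survival.** ICI response (RECIST CR/PR = R vs SD/PD = NR)
is predicted by repeated stratified cross-validated classifiers on
signature-gene expression; AUC is the normalized Mann–Whitney U. Hub
genes are those selected by ≥ 3 of 5 feature-importance methods. The
prognostic model is an L1-penalized Cox fit with the risk score
Σᵢ βᵢ·xᵢ, a median (or maximally selected log-rank) high/low split,
Kaplan–Meier curves, the log-rank test and Harrell's C-index; an
elastic-net α grid plus stepwise Cox provides the model comparison.
Subtypes come from Monti consensus clustering with PCoA verification and
hypergeometric pathway enrichment.

Every input the pipeline consumes can be generated synthetically with
planted, recoverable structure (`egfrsig.synth`), so the whole stack is
testable without external cohorts.

## Worked example

```python
import egfrsig as es

# 1. simulate three single-cell cohorts and derive the signature
cohorts = [
    es.simulate_sc_cohort(es.SimConfig(
        n_genes=200, n_cells=2000, n_corr_genes=12, n_de_genes=12,
        corr_strength=0.7, de_log2fc=1.0, seed=d))
    for d in range(3)
]
parts = []
for i, cohort in enumerate(cohorts):
    cohort = es.qc_filter(cohort)                      # <300 genes or >20% mito
    mal = cohort.expr.columns[cohort.cell_labels == "malignant"]
    corr = es.spearman_table(cohort.expr[mal], cohort.truth.activity.loc[mal])
    de = es.malignant_upregulated(cohort)
    parts.append(es.dataset_signature(corr, de, f"d{i}"))
sig = es.merge_signatures(parts)
print(f"derived signature: {len(sig)} genes "
      f"(planted: {len(cohorts[0].truth.signature_genes)})")

# 2. predict immunotherapy response from the signature
ici = es.simulate_ici_cohort(es.SimConfig(
    n_genes=200, n_samples=600, n_planted_genes=12, response_effect=0.8, seed=7))
result = es.train_response_classifier(
    ici, sig.as_gene_set(),
    cv=es.CVConfig(folds=5, repeats=3, seeds=(0, 1, 2)))
print(f"cross-validated response AUC: {result.auc:.3f}")

# 3. risk score and survival stratification
fit = es.fit_l1_cox(ici.expr.loc[sig.genes], ici.survival, iterations=10, seed=0)
scores = es.risk_score(ici.expr.loc[sig.genes], fit)
groups = es.split_by_cutoff(scores, ici.survival, method="median")
lr = es.logrank_test(groups, ici.survival)
print(f"L1-Cox selected {len(fit.selected)} genes; "
      f"log-rank chi2 = {lr.statistic:.1f}, p = {lr.p:.2e}")
print(f"C-index = {es.cindex(scores, ici.survival):.3f}")
```

Output:

```
derived signature: 12 genes (planted: 12)
cross-validated response AUC: 0.904
L1-Cox selected 12 genes; log-rank chi2 = 583.0, p = 8.55e-129
C-index = 0.912
```

The derivation recovers exactly the 12 genes planted with both the
correlation (ρ_S = 0.7) and the malignant up-regulation (log₂FC = 1.0);
the same genes then drive response prediction (AUC ≈ 0.90 versus ≈ 0.5
for a null cohort) and survival separation of the median-split risk
groups.

A `egfrsig` console command exposes the same stages from the shell
(`egfrsig simulate sc|ici|crispr`, `score`, `derive-sig`, `crispr-rank`,
`train-response`, `select-hub`, `risk-model`, `km`, `prognostic-grid`,
`cluster`, `pcoa`, `enrich`, `infiltration`); see `egfrsig --help`.

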