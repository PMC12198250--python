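# Methods

This note documents the models, defaults and design choices behind
`egfrsig`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Single-sample enrichment scoring (`egfrsig.score`)

For one sample, genes are ordered by decreasing expression (average ranks
for ties; residual ties broken by gene identifier so row order never
matters). Walking that order, the score accumulates the difference
between a weighted in-set ECDF — increments proportional to
(rank magnitude)^α, normalized to sum to 1 — and a uniform out-of-set
ECDF with increments 1/(N − |S|). One scorer serves every place a
per-sample pathway-activity score is needed (EGFR activity, immune
infiltration, hallmark correlation); the kernel-density GSVA variant is
deliberately not implemented, since nothing downstream distinguishes the
two and the rank-walk form admits an exact brute-force oracle.

* `alpha` (default 0.25): the conventional weight exponent; `alpha = 0`
  makes the score a pure rank statistic, invariant to any strictly
  monotone transform of one sample's expression — a property the tests
  verify.
* Set genes missing from the matrix are dropped with a warning rather
  than raising: genome coverage differs between cohorts.
* Min–max normalization maps a constant score vector to 0.5 (defined,
  symmetric) instead of dividing by zero.

## Signature derivation (`egfrsig.derive`)

Per dataset, malignant cells only: Gx = genes with Spearman ρ against the
EGFR-activity score strictly > 0.2 at BH q < 0.05; Gy = genes with
malignant-minus-rest mean log₂ difference ≥ 0.5 (inclusive) at Wilcoxon
BH q < 0.05; Gn = Gx ∩ Gy. Across datasets, each gene's retained ρ values
are combined by geometric mean over the datasets where it appears in Gn —
not over all datasets, which would multiply by undefined values — and
genes with geometric mean > 0.4 are kept. `n_datasets` is reported so a
stricter support policy can be applied afterwards; no minimum support is
imposed by default. FDR is computed within each dataset.

Degenerate-input conventions, chosen so a 20k-gene scan never aborts:
constant gene or constant score → ρ = 0, p = 1; all-tied rank-sum test →
p = 1. Fold changes are differences of log-scale means (the usual
single-cell convention for log-normalized matrices), in log₂ units.

Cell QC removes cells with fewer than 300 detected genes or more than
20% mitochondrial reads (defaults; both configurable). Cell-type
annotation itself is out of scope — synthetic cohorts carry labels.

## CRISPR ranking (`egfrsig.crispr`)

Per screen column, observed log-fold changes are centered and scaled to
unit sample (n−1) standard deviation; missing entries (blank cells in
the TSV) stay missing and are excluded pairwise from the cross-screen
mean — never imputed. Genes are ranked ascending by mean z, ties broken
lexicographically by gene identifier for bit-reproducibility. The flag
count is floor(fraction · N) with fraction 0.06: flooring never
over-flags. Enrichment of a signature is the percent of its
ranking-present genes that are flagged. z-normalization is per screen
column; normalizing within study instead is a one-line change but was
not needed for any tested property.

## Response modelling (`egfrsig.response`)

Features are signature-gene expression, standardized per gene within
each cohort (a deliberate, simple stand-in for cross-cohort batch
correction: it removes per-cohort location/scale and keeps the merge
step testable). Cross-validation is stratified k-fold (default 5)
repeated over independent seeds (default 10); hyperparameters are tuned
by an inner 3-fold grid search inside each training fold, so the pooled
out-of-fold AUC is honest. AUC is computed by the rank (Mann–Whitney)
formula with half credit for ties; it equals pairwise enumeration
exactly. Four classifier families are exposed behind one interface —
logistic regression (the reference model), k-NN, Gaussian naive Bayes,
random forest; further families plug in via the same estimator/grid
contract.

Benchmarking trains one tuned model per signature on the training cohort
and applies it unchanged to each holdout; signatures are ordered by mean
holdout AUC, and a signature missing from a holdout's gene space is an
NaN cell, not an error.

### Feature importance and hub selection

Five methods score every candidate gene: per-gene discrimination
(|AUC − 0.5|), L1-logistic stability selection (nonzero-coefficient
frequency over 30 subsamples of 80%), random-forest permutation
importance, forward wrapper selection by CV AUC, and per-gene Gaussian
class-conditional log-likelihood gain. Hub genes are those selected by
at least 3 of the 5 — the consensus rule is the contract; the per-method
selection criteria are this package's own:

* per-gene-null methods (univariate AUC, NB gain): a gene is selected
  when its score exceeds the 95th percentile of its own label-permutation
  null (B = 200, seeded, fully vectorized) — calibrated at ~5% per-gene
  false selection, which the tests check;
* stability selection and RF importance: the null is pooled across genes
  with fewer refits (B = 20 / 10), still hundreds of null draws; the L1
  penalty is chosen adaptively (smallest C whose full-data support
  reaches max(2, p/10) genes) and identically inside each permutation
  run, so frequencies cannot saturate at 1 for planted and null genes
  alike;
* the wrapper's stopping rule (3-fold CV-AUC gain ≥ 0.01, at most 15
  steps) is itself the selection criterion.

The sparse methods' per-gene false-selection rate is below, not at, 5%;
the calibration test asserts ≈5% only where the per-gene null applies
and an upper bound elsewhere.

The 80/20 cohort partition uses round-to-nearest for the training size,
so a merged cohort of 772 patients splits 618/154 (floor-based
conventions would give 617).

## Survival modelling (`egfrsig.survival`)

Ties are handled with the Breslow approximation everywhere, which keeps
the partial likelihood identical to the brute-force grid/Newton forms
used for verification (lifelines' Efron-only fitter is therefore not
used for fitting). The L1/elastic-net Cox path comes from the
glmnet-style coordinate solver; the penalty λ minimizes the
Verweij–van Houwelingen cross-validated deviance
−2·(ℓ(all; β_fold) − ℓ(train; β_fold)), summed over folds and averaged
over re-randomized fold assignments (default 25 iterations — the
full-scale convention is 1000; 25 keeps routine runs fast and the
chosen λ stable to ~1 grid step on the tested problems). Per-gene
selection frequency across all fold fits is reported. Coefficients apply
to standardized expression; `risk_score` is the exact linear combination
and raises (naming the genes) if any fit gene is missing.

* Median split: cutoff = median, scores equal to the cutoff go to the
  low-risk group (deterministic tie rule).
* "Best" cutoff: maximally selected log-rank statistic over distinct
  scores within the 10th–90th percentile band; the band prevents
  degenerate splits, and the resulting p-value is descriptive only —
  the cutoff was chosen to maximize it.
* Kaplan–Meier via the product-limit estimator (patients censored at an
  event time remain at risk at that time); with no censoring it equals
  the empirical survival function, which is tested as an identity.
* Harrell's C: usable pairs require the shorter time to be an event;
  score ties score 0.5.
* Prognostic grid: elastic-net α ∈ {0, 0.1, …, 1} plus forward-AIC
  stepwise Cox (α = 0 is fit as pure ridge, since the coordinate solver
  requires a positive L1 fraction). Out-of-fold risk scores are pooled
  into one C-index per model; cross-validation is leave-one-out for
  n ≤ 300 and 10-fold above that. Per-model failures are recorded as
  NaN without aborting the grid. Tree/kernel survival learners are out
  of scope; the grid preserves the comparison structure with the
  penalized-linear family.

## Subtype analysis (`egfrsig.subtype`)

Consensus clustering follows Monti: 100 resamples of 80% of samples,
k-means with 10 restarts on each, consensus = co-clustering count over
co-sampling count; assignments cut an average-linkage tree of
1 − consensus; sharpness per k is the proportion of ambiguous clustering
(PAC, band 0.1–0.9). k-means is the pinned base clusterer for
determinism. PCoA is classical scaling of the double-centered squared
distance matrix; negative eigenvalues are returned for diagnostics and
their axes dropped. Group comparisons expose both the rank-sum test
(default) and Student's t, with BH correction across features and the
usual 0.05/0.01/0.001 star codes. Pathway enrichment is the one-sided
hypergeometric upper tail, identical to one-sided Fisher on the 2×2
table (a tested identity). External services (TIDE), mutation landscapes
and deconvolution are out of scope.

## Synthetic data (`egfrsig.synth`)

What it emulates: multi-cohort single-cell data (malignant/immune/
stromal labels; per-cell QC covariates), merged bulk ICI cohorts with
RECIST labels and survival, and genome-scale CRISPR screen sets — each
with planted, recoverable structure recorded in a `TruthRecord`.

* Background expression is log₂(1 + counts) with negative-binomial
  counts (dispersion 4, log-normal gene means around 5), treated as
  log-normalized downstream.
* The latent EGFR activity is a per-cell scalar: N(0,1) within cell
  type, shifted by +1.5 in malignant cells. Planted correlation uses a
  Gaussian copula against the *within-type residual* with Pearson
  ρ = 2·sin(π·ρ_S/6), so the configured value is the Spearman
  coefficient and correlation-only genes acquire no incidental malignant
  shift; the exact-recovery truth for derivation is the corr ∩ DE
  planted set. `noise_sd` does not attenuate the planted correlation
  (the copula noise is fixed at √(1−ρ²)); it applies to the bulk and
  CRISPR generators.
* ICI cohorts: P(R) = logistic(logit(0.4) + Σ effect·z_g) over
  standardized planted-gene expression; responders draw CR/PR at 30/70,
  nonresponders SD/PD at 50/50. Survival is exponential with hazard
  (1/365)·exp(Σ log-HR·z_g); censoring is an independent exponential
  whose rate is solved by bisection so the expected censored fraction
  equals the configured rate (default 0.3).
* CRISPR: planted resistance genes get mean LFC −2 (noise SD 0.5,
  17 screens — the scale of the published screen compendium); entries go
  missing independently at the configured rate, with one observation per
  gene always retained.

Every generator is a deterministic function of the seed, and the tests
verify bit-identical replay.

What the generators do **not** model — and hence what green tests do not
establish about real data: batch effects and their correction, ambient
RNA/doublets, annotation error in cell-type labels, non-proportional
hazards, informative censoring, correlated gene-gene structure beyond
the planted latent factor, and cohort-specific response-rate shifts.
Recovery results bound what the estimators can do under the stated
conditions; real cohorts are harder.

## Problem sizes and defaults used in the checks

The packaged checks run the derivation at 200 genes × 2000 cells × 3
datasets (12 planted genes), response modelling at n = 400–600 with
30–40 genes, L1-Cox recovery at n = 400 with 10 genes and 25 CV
iterations, the prognostic grid at n = 400 (10-fold), and the CRISPR
worked example at the genome scale of 22 505 genes × 17 screens. These
sizes make each planted effect comfortably identifiable while keeping a
full run of the suite a few minutes on one core.

## Packaged gene sets

`data/egfr_sets_synthetic.gmt` is a synthetic stand-in (and says so in
its description fields): the 12 hub genes and the 4 CRISPR-verified
resistance genes (MAT2A, JUNB, C12orf57, NR4A1) are the experimentally
reported members; the remaining symbols are canonical EGFR-pathway genes chosen
to reproduce the reference set sizes (36 scoring genes, 32 signature
genes, so 4/32 = 12.5%). The fixture supports scoring and enrichment
arithmetic; it is not the published supplementary gene list.

## Known limitations

* The ssGSEA walk is O(genes × samples) per set without batch-scoring
  optimizations; scoring thousands of sets over large matrices is slow.
* Stability selection's adaptive penalty rule targets moderate
  dimensionality (tens of candidate genes, hundreds of samples).
* The maximally-selected-cutoff p-value is biased by selection and is
  reported as descriptive; no min-p correction is applied.
* Consensus clustering stores dense n × n matrices; thousands of samples
  need a sparser accumulation strategy.
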