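# Methods

## Problem and scope

`pathometa` builds a binary pathogenicity metapredictor from the
categorical calls of eight functional-impact tools (FATHMM, SIFT,
PolyPhen-2 HDIV/HVAR, PROVEAN, MutationAssessor, MutationTaster, LRT) as
they appear in ClinVar-style VCFs annotated via SnpSift/dbNSFP
(`dbNSFP_<Tool>_pred` INFO keys). It benchmarks four feature
representations under a random-forest grid search, selects one model, and
reclassifies VUS/CI variants with a high-confidence probability rule. It
does not run the predictors themselves, parse dbNSFP score (non-`_pred`)
columns, or perform pathway enrichment on the reclassified genes.

## Data model and preprocessing

**Vocabularies.** Q = 8 predictors, J = 23 category codes. Severity
orders (most→least deleterious) follow tool semantics: FATHMM/SIFT D>T;
PolyPhen-2 D>P>B; PROVEAN D>N; MutationAssessor H>M>L>N; MutationTaster
A>D>N>P; LRT D>N>U. LRT's `D` is included because dbNSFP defines it, even
though some summaries list only N/U; `vocabularies(include_lrt_d=False)`
drops it. Multi-transcript calls (`,` or `&` separated) collapse to the
most severe code — the aggregation rule is a package choice (upstream
conventions vary) and is the conservative one for a pathogenicity screen.

**Labels.** CLNSIG strings group to four labels: benign (Benign,
Likely_benign, Benign/Likely_benign), pathogenic (mirror), vus,
conflicting. Compound strings such as `Pathogenic,_risk_factor` map by
their leading term (ClinVar's primary assertion); everything else is
excluded and counted in the exclusion report. Training uses complete cases
only (all eight calls present); duplicate genomic keys keep the first
occurrence to avoid train/reclassification leakage. Conservation holds by
construction: |train| + |reclass| + |excluded| = |input|.

## Encodings

* **label** (n×8): codes 0..k−1 in lexicographic category order.
* **one-hot** (n×23): indicator matrix Z, exactly one 1 per predictor
  block; row sums are Q.
* **MCA** (n×2): indicator-matrix correspondence analysis. P = Z/(nQ);
  r = 1/n, c = colsums(P); S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2); SVD S = UΣVᵀ;
  row principal coordinates F = D_r^(−1/2)UΣ, first two axes retained. New
  rows are projected by the transition formula F_new = (z/Q)·B with
  B = D_c^(−1/2)V the category standard coordinates; on the training rows
  this reproduces F exactly (the residual term lies in S's null space).
  Categories unobserved at fit time carry zero mass and zero loading.
  Total inertia Σσ² = (J_obs − Q)/Q; no Benzécri/Greenacre correction.
  Per-axis sign is fixed by making the largest-magnitude category loading
  positive, so fits are deterministic. Fitting requires ≥3 distinct rows
  and ≥2 positive singular values. MCA is fit on the train table only and
  applied to reclassification rows by projection.
* **autoencoder** (n×2): symmetric network 23→h→2→h→23, hidden sizes
  h ∈ {10, 20, 30} in the benchmark grid. A single hidden layer cannot
  emit a 2-D representation, so a 2-unit linear bottleneck is interposed
  between mirrored hidden layers — a design choice of this package, made
  to honor both the stated hidden sizes and the 2-D representation.
  Activations: rectifier, rectifier with dropout (rate 0.2 on the hidden
  layers only, off at inference), or tanh; output layer linear; loss MSE.
  Training is plain minibatch SGD (batch 32, learning rate 1e-3 default)
  over full shuffled passes, epochs ∈ {10, 20, 30} in the grid; weights
  are Glorot-initialized from a seeded generator, so a fixed seed gives
  bit-identical representations. Any optimizer satisfying monotone loss
  improvement would do; SGD is the simplest deterministic choice.

## Forest, evaluation, selection

Forests are bagged, fully grown CARTs (scikit-learn) with `mtry` candidate
features per split. RFprob is the fraction of trees voting pathogenic;
because fully grown trees have pure leaves, scikit-learn's averaged leaf
probabilities equal vote fractions, and unanimous rows score exactly 0
or 1. No probability calibration is applied — the RFprob ≥ 0.9 rule is
defined on raw vote fractions. Class imbalance is left uncorrected (the
intended training sets are only mildly unbalanced).

Each grid cell (encoding × encoder hyperparameters × trees × mtry) is
scored by stratified 10-fold CV ROC AUC (trapezoid; folds that end up
single-class are skipped with a warning) and by the OOB error of a
full-data fit. Defaults: trees 50..1000 step 50 (the step is a package
choice; only the endpoints are externally stated), mtry
{2, ⌊√d⌋, ⌊d/2⌋, d} deduplicated — the published grid "2, p, p/2, p"
contains a literal duplicate, read here as including the conventional √d.
Best = max AUC, ties broken by lower OOBE, then fewer trees, then smaller
mtry. Baselines: naive Bayes (Bernoulli on binary matrices, Gaussian
otherwise) and linear/RBF SVM, scored by the same CV AUC; SVM
probabilities use a monotone logistic of the margin, which leaves AUC
unchanged.

Gini importance is scikit-learn's normalized mean decrease in impurity;
for one-hot features the category columns of each predictor are summed,
so the report is per predictor and sums to 1.

## Reclassification

The selected (encoder, forest) pair scores each VUS/CI row. RFprob ≥ 0.5
⇒ pathogenic (the boundary is inclusive); high-confidence means RFprob ≥ t
or ≤ 1−t, default t = 0.9, with the boundary again inclusive.
`high_confidence_set` is monotone: lowering t only adds members. Because
published per-stratum percentages in this problem area are ambiguous about
their denominator, `summarize_reclassification` reports both the
per-stratum and the overall-denominator percentage.

## Synthetic generator

The generator states a class-conditional world: each variant has a true
class; a pathogenic variant's predictor emits its most severe category
with probability `concordance` and otherwise uniform over the remaining
categories (benign mirrors with the least severe). Calls are independent
across predictors given the class; missingness is independent
Bernoulli(`missing_rate`) per call. VUS/CI rows get the corresponding
CLNSIG strings plus a hidden fair-coin truth used only for recovery
scoring (it is not written to VCF). Positions are drawn uniformly without
collision per contig; ref ≠ alt from {A,C,G,T}. Defaults: class counts
mirror a genome-wide complete-case ClinVar split (18,891 benign / 16,471
pathogenic / 93,612 VUS / 7,193 CI); concordance 0.9 (the signal level at
which the package's own recovery criteria are stated) and missing rate 0.1
(moderate missingness; real dbNSFP annotation is often sparser). These
defaults were fixed once, before any test outcomes, and tests always pass
explicit values.

What the generator does *not* emulate: allele frequencies, linkage,
sequence context, per-predictor error correlation, review-status stars, or
realistic per-predictor missingness structure. A green recovery test
therefore establishes that the pipeline's machinery is correct and
well-calibrated under conditional independence — not that real ClinVar
variants are this separable.

## Numerical choices and limitations

* Singular values below 1e-12 are treated as zero in MCA.
* The AUC oracle in the tests (exhaustive pair counting with half-credit
  ties) and the MCA oracle (S assembled entry by entry, dense SVD) are
  independent re-derivations, kept apart from the library code paths.
* Determinism: one integer seed drives the simulator, fold shuffling,
  forest bootstraps and autoencoder init; reruns give byte-identical
  synthetic VCFs and identical grid results and manifests.
* OOB error is only defined for bootstrap ensembles; baseline models
  report CV AUC alone.
* With eight conditionally independent predictors at concordance 0.9 the
  Bayes error is tiny, so synthetic CV AUCs saturate near 1.0; real
  annotations are correlated between tools and yield lower AUCs.
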