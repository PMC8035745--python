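# Methods

## Overview

`lncfuse` implements an integrative lncRNA prognosis workflow for bulk
tumor/normal RNA-seq cohorts in five layers: (1) preprocessing and
differential expression, (2) expression correlation with
secondary-structure fusion, (3) network construction (co-regulatory,
ceRNA, pathogenic rescue), (4) a survival screening cascade ending in a
multivariate Cox risk model, and (5) a synthetic-cohort generator that
plants ground truth for every layer. This note records the model
assumptions, the defaults and why they were chosen, and what the tests
do and do not demonstrate.

## Preprocessing and differential expression

Counts are normalized by the trimmed mean of M-values (TMM), implemented
from its canonical definition: the reference sample is the column whose
upper-quartile count rate is closest to the cohort mean; per-gene
log-ratios (M) and average log-abundances (A) are doubly trimmed (30% on
M, 5% on A) and averaged with inverse delta-method variance weights;
factors are rescaled to geometric mean 1. No installed Python library
provides TMM, so it is implemented here and cross-checked in the test
suite both against an independent step-by-step implementation and
against `edgeR::calcNormFactors` through Rscript.

Expression is carried as log2-CPM with a prior count of 0.5 on
TMM-effective library sizes. Differential expression is a per-feature
Welch *t*-test on these values — deliberately plain, with no
empirical-Bayes moderation — with log2FC the difference of group means
on the log scale, consistent with the test's input. Benjamini–Hochberg
correction is applied **within** the mRNA and lncRNA classes separately,
because the two lists are thresholded and used independently downstream;
a `adjust_jointly` switch provides the pooled alternative. Dysregulation
requires adjusted *p* < 0.01 **and** |log2FC| > 1.5, both strict.
Tumor samples with overall survival below 10 days are excluded before
any analysis; normal samples carry no survival semantics and are always
kept.

## Correlation and thresholding

Spearman correlation is the tie-corrected version (Pearson of
mid-ranks); the classical closed form 1 − 6Σd²/(n(n²−1)) is exactly
recovered on tie-free data (a property test asserts agreement to
1e-12). Correlations are computed on tumor samples only, since they feed
tumor survival modelling. Constant features have undefined rank
correlation and propagate as NaN, which never counts as a threshold hit.

Thresholding at α drops every row (mRNA) and column (lncRNA) without a
single |C| ≥ α entry, but keeps sub-threshold entries inside surviving
rows and columns; the operation is idempotent. Retention uses ≥ (not >).
An input with no super-threshold entry yields an empty, flagged result
rather than an error.

## Secondary-structure scoring

The cofold engine is a weighted Nussinov dynamic program rather than a
full thermodynamic nearest-neighbour model: non-crossing base pairs with
energies GC = −3, AU = −2, GU = −1 (model units), a minimum of 3
unpaired positions enclosed by any pair, and the two transcripts (mRNA
first) joined by a 3-nt unpairable linker so intra- and inter-molecular
pairs compete in one fold. The choice is deliberate: the model is
self-contained and *exactly* testable — the DP is verified against
exhaustive enumeration of all non-crossing pairings on every random
sequence pair of total length ≤ 12. Strand-order symmetry is checked
empirically against the oracle, not assumed. The `mfe_fn` hook accepts
any callable with the same signature, so a true thermodynamic cofolding
engine can be substituted (energies then in kcal/mol).

The pair score E(m,l) averages MFE/(LEN_s + LEN_t) over all transcript
pairs of the two genes, then the E matrix is min–max normalized to
E′ ∈ [0,1]. The normalization is applied literally, which maps the
*least* stable duplex to E′ = 1; whether the inverse orientation is the
biologically intended one is genuinely ambiguous, so the literal formula
is the default and `invert_structure_scale` exposes the reverse. A
constant E matrix maps to all zeros, degenerating fusion to |C|.
Transcripts longer than the configurable 300-nt window are scored in
sliding windows with the minimum window score taken, bounding the cubic
DP cost.

## Fusion

AC(m,l) = max(|C|, E′) with the sign of C (C = 0 takes the non-negative
branch). Consequences asserted as invariants: signs are preserved,
|AC| ≥ |C| everywhere, the operation is idempotent and monotone in E′.
The adjustment summary classifies an entry as unchanged when
|AC − C| ≤ 1e-6; the tolerance matches the 6-decimal precision of the
bundled worked-example tables, where an unchanged value can still differ
by one unit in the last printed digit through rounding.

## Networks

The co-regulatory network is the bipartite graph of |AC| ≥ α entries
with signed weights. The ceRNA network joins user-supplied
lncRNA–miRNA and mRNA–miRNA target tables on miRNAs shared between the
dysregulated sets, with set semantics (row order and duplicates are
irrelevant). The rescue step recovers lncRNAs adjacent to pathogenic
mRNAs in the α = 0.7 co-regulatory network (configurable); this
re-admits lncRNAs whose marginal expression–survival association is weak
but which sit in pathogenic neighbourhoods. Database retrieval is out of
scope: target tables and pathogenic lists are plain TSV/text inputs.

## Survival screening and risk model

The cascade is: univariate Cox → RSF importance → lasso-Cox on the
union, then multivariate Cox on (lasso survivors ∪ rescued lncRNAs).

- **Univariate screen** uses the single-covariate Cox *score* test at
  β = 0 (the log-rank trend test) with Breslow tie handling, implemented
  directly (no installed library exposes it per covariate) and
  cross-checked against the lifelines Wald test. Threshold *p* < 0.05.
- **RSF screen** uses permutation importance (mean concordance drop,
  scaled ×100) of a random survival forest, thresholded at 9. The
  forest and permutation are seed-deterministic. Importance can be
  measured on a held-out fraction (`holdout`) for less optimistic
  values. Defaults: 1000 trees library-side; the pipeline and the
  synthetic studies use 200 trees, 2 repeats and a 50% holdout, which
  keeps the cascade tractable on a single core without changing which
  strong features pass.
- **Lasso-Cox** fits the regularization path with an elastic-net Cox
  solver (l1_ratio = 1) and scores each penalty by the cross-validated
  partial log-likelihood (Verweij–van Houwelingen: full-data likelihood
  of fold-trained coefficients minus training-fold likelihood). The
  default penalty rule is "largest within one standard error of the
  best", which favours sparsity; this is what makes the cascade
  null-safe — with pure-noise candidates the null model wins and the
  selection is empty, so univariate false positives cannot reach the
  (selection-biased) multivariate stage. `rule="best"` and a forced
  `alpha` are available.
- **Multivariate Cox** (lifelines, Efron ties) drops covariates with
  Wald *p* > 0.8 and refits once — a single pruning pass for clearly
  uninformative covariates — then reports as the signature the subset
  with *p* < 0.05, refit so the reported coefficients are the risk-score
  weights. Exactly duplicated covariates raise an error naming the pair.

Risk scores are the linear predictor Σβ_j·e_ij; risk levels dichotomize
at the cohort median with ties assigned to high risk. Kaplan–Meier
curves use the product-limit estimator and two-group log-rank tests
(lifelines), verified against a hand product-limit computation. The
independence analysis runs per-variable and joint Cox fits of the risk
score against numerically coded clinical covariates; constant columns
are excluded with a warning. Train/test splits are random, stratified by
event status, seed-deterministic, with singleton strata assigned to the
training set.

## Synthetic cohorts

The generator emulates the reference study design: 451 tumor and 41
adjacent normal samples by default, negative-binomial counts with
gene-specific log-normal means (lncRNAs at half the mRNA scale,
dispersion 0.1), planted up/down genes at |log2FC| = 2 chosen among
reasonably expressed genes (base mean ≥ 20, where a fold change of this
size is detectable), co-expressed lncRNA–mRNA pairs induced by a shared
log-scale Gaussian factor (σ = 0.7; pair members floored at a base mean
of 100 so their rank correlation is observable over counting noise), and
reverse-complement blocks
embedded in a subset of those pairs' transcripts. Planted pairs and
signature lncRNAs are drawn from the dysregulated sets when possible, so
the downstream stages that only see dysregulated features can encounter
them. Survival is exponential proportional hazards on the z-scored
log2-CPM of the signature lncRNAs (coefficients are per-SD log hazard
ratios; baseline hazard 0.0015/day gives a realistic median of roughly
two years), with uniform(0, τ) censoring where τ is bisected to the
target censoring rate (0.7 by default, typical of observational tumor
cohorts). Stage I–IV labels follow a 0.2/0.3/0.3/0.2 ordered-latent
scheme correlated with the linear predictor so the independence analysis
has non-trivial structure. The standalone `simulate_survival` applies
coefficients to the supplied expression values untransformed, so
parameter-recovery tests read back β on the caller's scale.

What the generator does **not** emulate: GC/length biases, isoform
structure, batch effects, non-proportional hazards, or informative
censoring. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness
to the full messiness of real cohorts.

## Study conditions used by the validation suite

The cohort-scale checks run at 300 tumors × 200 candidate lncRNAs with
5 planted signature lncRNAs (|β| = 0.5 per SD) and 30% censoring,
20 seeds per condition; the differential-expression recovery check uses
50 + 50 samples × 1300 features. These sizes make each cascade run take
a few seconds while leaving the statistical questions (recovery,
null-safety, calibration) non-trivial. Cohort-level result counts from
any specific patient dataset are not reproducible from synthetic data
and are covered instead by the invariants (set algebra of the stage
counts, sign/magnitude properties of fusion, oracle equivalences).

## Numerical choices and degenerate inputs

- BH adjustment delegates to statsmodels; Spearman and Welch tests to
  scipy; Cox/KM to lifelines; RSF and elastic-net Cox to scikit-survival.
- The fusion summary tolerance (1e-6, ≤ with a 1e-12 float guard) is a
  printing-precision convention, not a model parameter.
- Constant features: NaN correlation (excluded), warning + exclusion in
  the univariate screen and independence analysis.
- Empty outcomes are flagged, not raised: empty thresholded matrix,
  empty network, empty lasso selection, empty final signature (the
  risk model then has no coefficients and an undefined cutoff).
- All randomness flows from explicit integer seeds; identical configs
  give bitwise-identical cohorts and byte-identical pipeline reports.

## Known limitations

- The base-pair-counting fold model ranks duplex stability only
  coarsely; absolute energies are not thermodynamic.
- The literal min–max orientation of E′ (least stable ⇒ 1) is kept for
  fidelity to the fused-statistic definition; users who want the
  intuitive orientation must set `invert_structure_scale`.
- The univariate screen's score test and the multivariate Wald tests are
  asymptotic; at very small cohorts (tens of samples) the cascade is
  underpowered and legitimately returns empty signatures.
- Lasso penalty selection by the 1-SE rule is conservative; very weak
  true effects can be dropped in favour of null-safety.
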