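# Methods

## Scope and model of the data

`panelforge` treats a quantitative-proteomics biomarker study as four
statistical stages downstream of the instrument: quality control of a
protein × sample abundance-ratio matrix, a two-group differential
screen, consensus feature selection by three classifiers, and
validation of the resulting marker panel on independent IHC H-scores.
Everything upstream (sample preparation, acquisition, database search)
and everything ornamental (pathway enrichment, figure aesthetics) is
out of scope.

Abundances are TMT reporter-ion ratios to a pooled reference channel,
so a protein with no biological signal sits near ratio 1. The
synthetic generator models this directly as log2-normal ratios:

    ratio = 2 ** (batch_shift + group_effect + noise)

with per-(protein, batch) shifts ~ N(0, `batch_sd`), within-group noise
~ N(0, `noise_sd`) on the log2 scale, a ± `effect_log2fc` group effect
for a planted subset of proteins (sign drawn per protein; +1 means up
in the lmCRC group), pooled samples at the per-protein global mean plus
N(0, `pool_sd`), and technical replicates equal to their source sample
re-measured under the target batch's shift plus N(0, `tech_sd`).

### Generator parameters

| parameter | default | meaning |
|---|---|---|
| `n_group_a`, `n_group_b` | 22, 17 | study samples per group (PAIM / lmCRC) |
| `n_batches`, `n_pools` | 3, 3 | 16-plex batches; one common pool each |
| replicates | 3 intra + 3 inter | technical re-measurements |
| `n_proteins` | 7,871 | quantified proteins |
| `missing_rate` | 0.057 | fraction of cells set missing, completely at random |
| `outlier_rate` | 0.026 | fraction of cells spiked into the upper tail |
| `n_planted` | 105 | proteins with a true group effect |
| `effect_log2fc` | 0.6 | planted effect; must exceed 0.25 to be callable |
| `noise_sd` | 0.25 | within-group SD, log2 scale |
| `batch_sd` | 0.1 | batch-shift SD, log2 scale |
| `tech_sd` | 0.05 | replicate noise (~5% CV), log2 scale |
| `pool_sd` | 0.02 | pool noise, log2 scale |

The design defaults (group sizes, batch/pool/replicate structure,
protein count, missing and outlier fractions) reproduce the emulated
study; the effect and noise scales are chosen so that a planted protein
at the default settings is comfortably but not trivially detectable at
the |log2FC| > 0.25 threshold (per-feature standardised effect
0.6/0.25 = 2.4). Outlier cells are multiplicative spikes (×6–12), upper
tail only, because the QC rule enforces a single upper cutoff and
ratios are bounded below by zero. Missingness is completely at random:
no mechanism is asserted by the emulated design, and MCAR is the
assumption under which mean-based fold changes stay unbiased. The
generator does **not** model peptide-level quantification, isotopic
impurity, intensity-dependent missingness or correlated protein
modules; passing tests therefore demonstrate correctness of the
statistics and error control under a clean ratio model, not robustness
to those real-data pathologies.

IHC tables are generated per marker from a binormal latent model
(class separation `mu = sqrt(2) * Phi^-1(target AUC)`), squashed
monotonically into [0, 300] and decomposed exactly into weak/moderate/
strong percentages (H ≤ 100 all-weak, 100–200 weak+moderate summing to
100% of cells, >200 moderate+strong). Monotone transforms leave the
AUC at its target; a target of exactly 1.0 instead draws the two
groups from disjoint uniform supports so the empirical AUC is 1 by
construction.

## Quality control

The outlier fence is **global**: Q3 + k·IQR (k = 2 by default,
linear-interpolation quartiles) over the pooled distribution of all
present cells, because the procedure being reproduced reports a single
cutoff and a single outlier percentage. Values above the fence are
replaced by the fence (idempotent); missing cells are untouched; no
lower fence is enforced. CVs use the sample SD (n−1): per protein
across the pool columns, and per technical-replicate pair over the
proteins present in both columns, with a 20% pass threshold on the
median.

Pipeline order is fixed: fence imputation on the full matrix
(pools and replicates included), differential testing on
pairwise-complete values, and 0.8×min missing-value imputation applied
to the study submatrix only when entering feature selection — the
imputation rule belongs to the classification phase, while the Welch
test handles missingness by per-protein deletion. Whether the original
cutoff was computed before or after excluding QC columns is not
recorded anywhere; computing it on the full matrix is this package's
documented choice.

## Differential screen

Welch's unequal-variance t with Welch–Satterthwaite df, two-sided,
computed on the **raw** ratios by default because the fold change is
defined from raw ratio means (`log_scale=True` switches the test to
log2 ratios). Proteins with fewer than two present values in either
group, or zero variance in both, are marked untested (NaN p) and
excluded from the Benjamini–Hochberg family rather than diluted in as
p = 1. DEP calls use strict inequalities at both thresholds
(adjusted p < 0.05, |log2FC| > 0.25). The UMAP embedding is a seeded,
single-threaded run on the z-scored DEP submatrix; it is a
visualisation aid, delegated entirely to `umap-learn`.

## Consensus selection

All three selectors see per-protein z-scored abundances (z-scoring
across samples is the standard feature-scaling axis) and draw every
random decision from one seed.

**Random forest.** Scaled permutation importance in the classic
R-randomForest sense: per tree, out-of-bag accuracy minus accuracy
with one feature permuted among the OOB rows; the per-tree decreases
are averaged and divided by their standard error across trees. Note
this statistic grows like sqrt(n_trees) for a fixed signal, so the
MDA > 3 selection threshold is calibrated to the conventional
1000-tree forests (the package default); scaled-down test runs use
≥250 trees. Stage 2 runs 50 stratified 4:1 hold-out splits
(stratification is required — an unstratified 8-sample test set can
lack a class entirely, leaving the AUC undefined), re-selects
MDA-passing features on each training set, and retains iterations with
held-out accuracy and AUC exactly 1 (probability scores, midrank
ties). The reported feature set keeps proteins with inclusion
frequency ≥ 50% of retained models; the full frequency table is always
in the metadata. Zero retained models is a reported diagnostic, not an
exception.

**LASSO.** L1-penalised logistic regression over a geometric lambda
path from the null-gradient lambda_max down to 0.01·lambda_max,
10-fold stratified CV, mean held-out binomial deviance as the
criterion, and the one-standard-error rule (largest lambda within one
SE of the minimum). Members are the nonzero coefficients refit on all
samples at that lambda.

**SVM.** The original posterior-probability gene ranking is replaced
by a documented univariate ranking — absolute Welch t on the training
split, pluggable via `rank_fn` — feeding a forward search: linear SVMs
on ranked prefixes, evaluated on stratified 80/20 splits over 6
sampling iterations (a fixed, configurable count). The minimum
classifier is the smallest prefix size attaining the lowest mean
held-out error; members are the k* proteins with the highest inclusion
frequency among per-iteration top-k* sets.

**Consensus.** A protein enters the panel with ≥2 algorithm votes;
direction comes from the DEP-table fold-change sign; output order
(votes desc, then id) is invariant to the order of the input sets.

A structural property worth knowing: when a single protein separates
the groups almost perfectly (per-feature standardised effect ≳ 3), the
LASSO 1-SE rule and the SVM minimum classifier intentionally return
very small sets, so redundant true markers can end up with only the
random-forest vote and fall out of the ≥2-vote panel. Full recovery of
a redundant planted set through the consensus is therefore *not*
guaranteed at large effect sizes — minimality and completeness pull in
opposite directions. The null direction is only partly protective:
with permuted labels the random forest retains essentially no perfect
hold-out models, but the LASSO and the SVM search the same sample and
therefore tend to agree on the same spuriously separating proteins, so
their false positives are positively correlated and the two-vote panel
is non-empty in a substantial fraction of permuted-label runs (roughly
half at 300 proteins and n = 39). Multi-algorithm voting reduces, but
does not null out, false discovery; small consensus panels on weak
data should be read with that in mind.

## Validation statistics

The DeLong machinery is implemented from structural components: AUC as
the Mann–Whitney statistic with ties at 1/2 (computed in the
single-division rank form so it agrees exactly with pair enumeration),
variance var(V10)/m + var(V01)/n from the per-case placement values,
and the correlated-curve comparison z = (A1 − A2)/sqrt(v1 + v2 − 2c)
with the covariance from shared components. Reported AUCs are oriented
to ≥ 0.5 (the raw value and scoring direction are retained); the 95%
normal CI is truncated to [0, 1], which under perfect separation
degenerates to [1, 1]. No multiple-testing correction is applied
across markers by default.

Fisher's exact test is the two-sided hypergeometric test; zero-margin
tables report p = 1 with a flag. The rank-sum test enumerates exactly
for tie-free groups of ≤ 20 and otherwise uses the tie-corrected
normal approximation. The multimarker combination is a
maximum-likelihood logistic fit on H-scores; complete or
quasi-complete separation (expected whenever an AUC-1 marker like a
perfectly discriminating stain is included) is detected, the
coefficients are reported non-finite, and the ROC is still summarised
from a lightly ridge-penalised separating direction, which leaves the
AUC well-defined. Sample clustering is average-linkage on correlation
distance 1 − r, cut at two clusters.

## Numerical choices and degenerate inputs

- Quartiles: linear interpolation between order statistics, recorded
  in the QC report.
- Constant proteins z-score to 0; constant features in the SVM ranking
  sink to the bottom rather than erroring.
- liblinear is run with a fixed internal seed and tolerance 1e-5 so
  identical configs give bit-identical outputs.
- `bh_adjust` preserves input order and returns NaN for untested
  entries; adjusted values are monotone-enforced and capped at 1.
- Degenerate DeLong variance (se = 0): p = 0 unless AUC = 0.5, CI
  collapses to the point estimate.
- All counts/rates are validated up front; empty matrices, all-missing
  matrices, single-class label vectors and zero-variance cluster
  inputs raise `ValueError` with a named cause.

## Problem sizes used in tests

The test suite runs the full design at reduced width: 150–400 proteins
with 4–20 planted markers for pipeline and recovery tests, 2,000
proteins × 20 seeds for the null screen, 250-tree forests for the
selection loops, 2,000 replicates for the DeLong calibration, and
1,000 random instances per statistic for the oracle comparisons. The
acceptance script uses 1,200 proteins with 60 planted markers and the
published validation-cohort sizes (11 vs 19) for the IHC arm.

## Known limitations

- MCAR missingness and independent planted effects are idealisations;
  intensity-dependent missingness and correlated protein modules would
  weaken both the DEP screen's power claims and the selector
  comparisons.
- The scaled-MDA threshold depends on forest size (see above); results
  quoted at other tree counts are not directly comparable.
- The SVM selector's univariate ranking is a deliberate substitute for
  the original package's class-conditional posterior ranking; with the
  ranking pluggable, any monotone separability score can be swapped in.
- In-sample AUCs from the logistic combination are optimistic; no
  internal cross-validation is applied to the combined score.
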