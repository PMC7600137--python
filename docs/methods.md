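# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
a reimplementation would need to reproduce results exactly.

## Study design emulated

Two clinical groups — cases sampled at two timepoints (T0 before and T1
after a treatment course; default n = 26 subjects) and controls sampled
once (default n = 16) — plus replicate injections of a pooled
quality-control (QC) sample (default 8). Features are untargeted LC-MS
variables identified as `time@mass` (retention time in minutes @ m/z in
Da), analyzed separately per ionization mode (default table size 108
features, the negative-mode panel size of the emulated design). Three
contrasts are run: T0 vs control and T1 vs control (unpaired) and T0 vs
T1 within cases (paired).

## Synthetic data model

Intensities are log-normal per feature: feature j has a baseline
log-mean μ_j ~ N(11, 1.5²) (≈ three decades of dynamic range around
6·10⁴ counts) and total within-group log-scale standard deviation
σ = 0.5, split into a subject random intercept and a residual with
intraclass correlation ICC = 0.5 (so paired samples of one subject
share half their log-scale variance — the structure multilevel analysis
exploits). A chosen subset of `n_discriminating` features (default 10)
is shifted in cases by `effect_size · σ` (default effect 1.5,
standardized units); an optional `paired_effect` shifts the same
features between T0 and T1 within cases (default 0, the emulated
study's null finding).

QC replicates are drawn around the pooled mean profile with a
raw-scale technical CV of 0.10 per feature, except for a
`qc_cv_high_fraction` (default 10%) of features given CV 0.40 so the
QC filter has genuine removals to make. No injection-order drift or
batch structure is simulated.

**Missingness.** The default mechanism is left-censoring: cells whose
simulated intensity falls below the global `missing_rate` quantile of
all study-sample intensities (default rate 0.10) are recorded as
missing. This is the mechanism the pipeline's imputation step assumes —
missing LC-MS values read as "below detection", which is why they are
imputed *below the feature minimum* — and it is what makes imputation
approximately rank-faithful. A `mcar` mode (completely random deletion)
is available as a stress test; under MCAR the below-minimum imputation
is deliberately misspecified and injects multi-log-unit noise, which
measurably degrades both univariate power and PLS-DA performance. QC
rows are never censored so the CV filter is defined for every feature.

What passing tests on this generator do **not** show about real data:
no chromatographic peak-shape or retention-drift artifacts, no
correlated feature blocks (adducts/isotopologues of one metabolite), no
batch effects, and effect sizes are homogeneous across planted
features. Recovery rates on real tables can be lower for all these
reasons.

## Preprocessing

Order is enforced (out-of-order calls on pipeline tables raise):

1. **QC CV filter**: per feature, CV = sd/mean over observed QC
   intensities, sample standard deviation (n−1); features with
   CV > 0.25 are excluded, as are features with no QC signal or zero QC
   mean (with reasons recorded). At least 2 QC injections are required.
2. **Imputation**: each missing cell is replaced by a uniform draw in
   (0, feature minimum), seeded. "Random number between zero and the
   minimum" is read as uniform.
3. **PQN**: per sample, quotients to a reference spectrum over features
   with positive reference; the sample is divided by the median
   quotient. The reference defaults to the median spectrum of the study
   samples (QC rows are dropped after the filter and do not influence
   normalization).
4. **Log + center**: natural log (base is irrelevant downstream up to
   scale: centering, rank tests and PLS directions are invariant), then
   per-feature mean centering.

Imputation before PQN: PQN needs a complete positive matrix, and
imputing first lets the quotients use all features. The alternative
order (PQN on observed entries only) is not implemented.

Targeted branch: below-LOQ values (missing or < LOQ) are imputed
uniformly in (0, LOQ), then autoscaled (mean 0, sd 1, n−1 convention;
constant analytes are dropped with a warning).

## Univariate screening

Mann–Whitney (unpaired) or Wilcoxon signed-rank on T1−T0 differences
(paired), two-sided. Exact null distributions are used when the sample
is small (combined n ≤ 20) and tie-free; otherwise the tie-corrected
normal approximation with continuity correction — the regime of the
default 26-vs-16 design. Zero differences are dropped (Wilcoxon's
convention); a feature with all-zero differences gets p = 1. Two-sided
p = min(1, 2·min(tail probabilities)). BH step-up q-values:
q_(i) = min_{j≥i} m·p_(j)/j capped at 1; significant ⇔ q ≤ δ with
δ = 0.10.

## PCA outlier screening

Per analysis group, PCA on centered data. The component count is the
smallest A explaining ≥ 80% of variance (capped to leave a residual
subspace and at 10), or fixed by the caller. Limits at α = 0.05:

* T² limit: (A(n−1)(n+1)/(n(n−A))) · F_{A,n−A,1−α},
* Q (squared residual) limit: Jackson–Mudholkar approximation from the
  residual eigenvalues.

A sample exceeding either limit is flagged and dropped before the
univariate and multivariate stages. Note these are prediction-type
limits: applied to the training samples themselves at small n they are
conservative (top eigenvalues are over-estimated, so flag rates run
below α — roughly 2% at n = 30 for nominal 5%); calibration to α is
recovered as n grows, which is what the test suite verifies at n = 300.
Degenerate α values short-circuit: α ≥ 1 flags everything, α ≤ 0
nothing.

## PLS-DA

Single-response NIPALS PLS1 with classes coded −1/+1 (equivalent to the
two-column dummy coding for two classes and simpler); X and y centered
on the training data, no scaling beyond the global preprocessing.
Sequential extraction: w ∝ Xᵀy (unit norm), t = Xw, loadings
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflation X ← X − tpᵀ. Extraction stops
early if no covariance remains. Predicted class = sign of the fitted
response (threshold 0). At full rank the fit coincides with least
squares, which the tests verify. Default A = 2 latent variables (the
display choice of the emulated study); `AnalysisConfig(A=None)` instead
picks A ∈ {1..5} by maximal cross-validated MCC.

**VIP**: VIP_j = √(p Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = q_a²·t_aᵀt_a; Σ_j VIP_j² = p identically.

**Post-transformation**: the A-dimensional score space is rotated
(orthogonal R, first direction ∝ Tᵀy) into one predictive score with
maximal covariance with the coded response and A−1 orthogonal scores
with zero covariance with it. Fitted values and class predictions are
invariant (verified to < 1e−10). A = 1 returns the identity with a
warning.

**Structured-noise diagnostic** (advisory): share of X variance carried
by the response-orthogonal directions, compared against a null obtained
by independently permuting each feature column (which destroys
between-feature correlation). A small permutation p flags a systematic
orthogonal factor, in which case VIP ranking deserves caution; no
alternative importance measure is provided.

## Validation statistics

**MCCcv**: stratified K-fold (default 5) with centering re-estimated
inside each training fold; held-out predictions pooled into one
confusion matrix. **Permutation test**: the same CV statistic under
label permutation, p = (1 + #{null ≥ observed})/(1 + n_perm), default
n_perm = 1000 — so the smallest attainable p is 1/1001. For paired
(multilevel) data, folds are assigned to whole subjects and the
permutation flips each subject's signed pair, the exchangeable null of
that design.

## Stability selection

For each of B = 200 bootstrap subsamples (stratified within class,
drawn with replacement; subsamples missing a class are redrawn with
bounded retries), a PLS-DA model is fitted in-bag and features with
VIP > 1 (the conventional VIP relevance cut) are marked selected. The
per-feature selection frequency is compared to a null distribution:
the same procedure is run on class-permuted labels n_null = 20 times
(b_null = B subsamples each) and all null frequencies are pooled across
features and runs; the relevance threshold is the (1−α) pooled quantile
with α = 0.05, and features strictly above it are *relevant*. Pooling
across features trades per-feature resolution for a much better
estimated null at fixed compute; with exchangeable null features the
two readings agree.

Out-of-bag samples are classified per subsample; each sample's class is
the majority vote over the subsamples that held it out (exact ties go
to the sign of its summed fitted responses), and MCCoob is the MCC of
those votes. For multilevel data whole subjects are resampled, so a
difference row and its mirror are never split between in-bag and
out-of-bag — splitting them would leak the answer, since the mirror of
a training row is classified trivially.

Under the null the relevant set averages ≈ α·p features (the expected
false-positive load; "empty up to the calibration level") and MCCoob is
centered at 0 with spread ≈ 0.19 at the default design — |MCCoob| can
exceed 0.25 in roughly a fifth of null runs, which is why single runs
should not be over-read.

## Annotation

Adduct algebra with proton 1.007276 Da, H₂O 18.010565 Da, NH₃
17.026549 Da: M−H (negative mode) gives M = m/z + 1.007276; M+H,
M+H−H₂O, M+H−NH₃ (positive mode) give M = m/z − 1.007276 (+ the lost
neutral where applicable). Default tolerance 20 ppm (QTOF-typical); all
polarity-consistent hits within tolerance are retained, sorted by
absolute ppm error; features without a hit are reported unannotated.
All annotations are Level 3 (accurate mass only). The bundled table
`data/ebc_asthma_markers_synthetic.csv` is a synthetic stand-in for a
database extract: its six neutral masses are back-calculated from
reported marker m/z values under their adduct rules rather than taken
from HMDB/METLIN records (live database queries are out of scope).

## Pipeline conventions

Contrasts run per ionization mode, never pooled. The merged relevant
set is the union of the univariate significant set and the multivariate
relevant set; whether the multivariate set is contained in the
univariate one is reported, not enforced. All seeds, parameters and
the operation list are embedded in each result's provenance block, and
a rerun with the same config is byte-identical.

## Problem sizes used in validation

The test suite validates type-I error over 200 simulated null studies
and power over 50 (unpaired) / 25 (paired) planted studies at the full
emulated design (26+26+16 samples × 108 features). Inside these
simulation loops stability selection uses a scaled-down ensemble of
B = 50 bootstrap subsamples with 5 permuted calibration runs — the
selection-frequency estimates are coarser but unbiased, and single-fit
checks and the acceptance script use the full B = 200 / n_null = 20
defaults. Oracle-equivalence tests compare each core statistic with an
independent brute-force implementation (enumeration of group
assignments for the exact Mann–Whitney null, of sign vectors for the
Wilcoxon null, step-up scans for BH, exhaustive scans for annotation)
on ≥ 1000 random small instances.

## Known limitations

* The relevance criterion inside stability selection (frequency vs a
  permutation-calibrated threshold) is one reasonable operationalization
  of "relevant at α = 0.05"; rank-based alternatives would select
  slightly different sets.
* The PCA limits are conservative in-sample at small n (above).
* No retention-time alignment, peak picking, adduct/isotope grouping or
  batch correction: tables are assumed to arrive feature-extracted and
  mode-separated.
* Two-class designs only; no multi-class PLS-DA, no O-PLS fitting (the
  post-transformation of a fitted PLS-DA covers the interpretability
  use case), no kernel variants.
* Annotation is accurate-mass only and inherits every ambiguity of
  that evidence level.
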