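# Methods

## The classification-based association scan

Classical GWAS regresses a scalar phenotype on genotype and reports a
p-value per variant. `imgwas` inverts the roles for high-dimensional image
phenotypes: the genotype defines a two-class labeling of the images, and
association strength is the out-of-sample classification performance of a
model trained to separate the classes. The underlying assumption is that
images of carriers and non-carriers are draws from two distributions
*E*ⱼ and *F*ⱼ; *E*ⱼ = *F*ⱼ is the null. A classifier that generalizes to
held-out subjects certifies *E*ⱼ ≠ *F*ⱼ without specifying in what way the
distributions differ — which is exactly what makes the approach applicable
to textural and non-linear effects that per-pixel univariate tests miss.

Genotypes are pooled under a dominant model by default (AA vs Aa+aa). This
keeps the task binary and mitigates class imbalance at low minor-allele
frequencies, where the aa class alone would be tiny; a recessive pooling
(AA+Aa vs aa) is available. Subjects missing the call at a SNP are dropped
from that SNP's task before splitting.

### Splitting

Each SNP task draws a subject-grouped split at ratios 7:1:2
(train/validation/test) by largest-remainder rounding over a seeded
shuffle. Grouping by subject is essential with longitudinal data: repeat
scans of one subject are highly correlated, and letting them straddle the
train/test boundary would leak identity information and inflate every
metric. The split seed is derived deterministically from (global seed, SNP
id), so scans are reproducible and resumable row by row. Splits are not
stratified by class by default; a stratified option exists for very low
MAF tasks.

### Classifiers

Two classifiers satisfy the same fit/predict contract:

- **Reference CNN** — three valid-padded 3×3 convolution blocks with 8, 16
  and 32 filters, each followed by ReLU and 2×2 max pooling; flatten;
  dense-128 ReLU; dropout 0.5; dense-2 softmax. Trained with Adam
  (default learning rate 1e−4, batch 32) for at most 30 epochs, early
  stopped when validation loss has not improved for 10 epochs, and restored
  to the best-validation epoch (selection by validation MCC is an option).
  The architecture is fixed across SNPs so performance values are
  comparable between tasks. The implementation is pure numpy with
  hand-derived backpropagation; it is deterministic given the seed and
  exposes the last conv layer's feature maps and score gradients for
  saliency. Loss is two-class cross-entropy; no class weighting (the
  dominant pooling already reduces imbalance); no pre-training.
- **Linear stand-in** — ridge regression (alpha 1) on flattened pixels, for
  scans where training hundreds of CNNs is wasteful. Each fit uses a seeded
  random half of the training scans (bagging-style). This subsampling is
  deliberate: the fine-tuning test below compares repeated retrains, and
  retrain-to-retrain variability must dominate the chance alignment of any
  single labeling for that t-test to be calibrated. The CNN gets such
  variability from random initialization and batch order; a fully
  deterministic ridge fit does not, and with it the null fine-tuning
  p-values were markedly anti-conservative. Half-sampling restores
  calibration (checked: ~10 % of null tasks at p < 0.05, one-sided KS
  against uniform p = 0.77 at 40 null SNPs).

### Metrics and the fine-tuning test

MCC and macro F1 are computed from the test-set confusion matrix with
explicit degenerate-case conventions: MCC is 0 whenever a marginal sum is
zero, and a per-class F1 with undefined precision or recall is 0. These
conventions keep every scanned task scorable even when a model collapses
onto one class. The printed form of the MCC denominator in some sources
swaps a term; the standard √((tp+fp)(tp+fn)(tn+fp)(tn+fn)) is used.

The fine-tuning test retrains the classifier n_real times on the true
labels (same split, fresh training seed) and n_perm times on permuted
labels (fresh permutation each repetition; class proportions preserved),
then applies a one-sided Welch t-test per metric, real > permuted. Twenty
repetitions each are the default; tests use 5+5. Permutation is applied to
*subject* labels so all scans of a subject move together — permuting
individual scan labels would break within-subject exchangeability under
the grouped split (an image-level option exists for comparison). Because
the procedure is expensive, it is intended for a small top-ranked fraction
of the scan, not genome-wide.

A caution on permutation nulls: permuting the labels of a *perfectly
separable* task leaves ~1/√n excess agreement with the truth, and a
classifier can amplify that into high test MCC (the Bayes rule under
symmetric label noise below 50 % is still the true labeling). Permuted
retrains are therefore a null for "classifiable beyond chance", not a
guarantee of MCC ≈ 0 on arbitrarily strong tasks; MCC ≈ 0 under permutation
is expected when labels are independent of the images, which is the regime
the calibration tests exercise.

## Univariate simulation: testing vs classification

To relate the classification scale to the familiar p-value scale, both
strategies run on the same univariate samples: a major class from N(0, 1)
and a minor class from N(μ, 1), μ ∈ [0.2, 2], total n ∈ [3000, 7000],
major-class proportion 0.5–0.9. Per sample, a two-sided Welch t-test gives
p, and a depth-2 decision tree (minimum leaf 5) trained on a stratified
70 % subsample gives MCC/macro F1 on the held-out 30 %. The closed-form
Gaussian KL divergence (μ²/2 at unit variance) accompanies each record.
Over the default grid the Spearman correlation between −log10 p and MCC is
≈ 0.90 (seed-stable at 0.89–0.90). The correlation is diluted by the
strongly imbalanced cells, where the shallow tree predicts the majority
class at small-to-moderate μ and MCC sits exactly at 0 while −log10 p still
varies; within individual (n, proportion) strata the correlation ranges
0.87–0.98. Deeper trees, resubstitution scoring and exact log-space
p-values were tried and move the pooled value by < 0.01. Tree depth and
holdout protocol are fixed for reproducibility; p-values are floored at
1e−300 before the log transform.

## The synthetic cohort generator

The generator stands in for a restricted-access imaging-genetics cohort
and defines the conditions under which the framework is validated. It
emulates:

- **HWE genotypes**: per SNP, alt-allele frequency drawn uniformly from
  the MAF range (default 0.05–0.5), genotypes Binomial(2, p), independent
  SNPs; missing calls planted at rate 0.02.
- **Subject anatomy**: a shared smooth template (Gaussian-filtered white
  noise, σ = 4 voxels) plus a per-subject smooth deviation field of
  amplitude 0.2 — subject identity that repeat scans share.
- **Anchored intensity extremes**: the template carries three bright and
  three dark fixed reference structures on the central axes (amplitude 6),
  so every middle slice contains at least one of each. Real MR slices have
  intensity extremes set by stable tissue classes; a pure smooth field does
  not, and its extremes are then noise-sensitive — which matters because
  the pipeline's per-image min-max normalization turns any class-dependent
  shift of the extremes into a global multiplicative cue. With anchored
  extremes (and bounded noise, below) a planted variance effect stays
  mean-preserving after normalization; without them it is detectable by a
  linear model through the rescaling alone.
- **Longitudinal scans**: 1 + Poisson(1.5) scans per subject; each scan
  adds independent bounded uniform noise of sd 0.05 (default).
- **Genotype-dependent effects**, dominant by default, applied from the
  true genotype even where the reported call is masked as missing:
  `mean_blob` adds β × a Gaussian bump (σ = radius/2) to carrier volumes —
  a linear mean-shift signal; `texture_variance` scales the noise sd inside
  the blob by √(1+β) for carriers — a mean-preserving, purely non-linear
  signal. At noise sd 0.2 and β = 8 the variance contrast is invisible to
  pixelwise t-tests (Bonferroni-null) and to the ridge classifier
  (MCC ≈ 0) but the CNN separates the classes (MCC 1.0 in tests) — the
  fixture demonstrating what classification adds over mean-based testing.

Volumes default to 64³ (slices 64×64) to keep single-CPU runtimes in
seconds; the shape is configurable. What the generator does *not* emulate:
MRI physics (Rician noise, bias fields), scanner/site effects, population
structure and LD, registration error. Passing tests therefore show the
framework behaves correctly under its stated assumptions — grouped
splitting prevents leakage, null tasks score near zero, planted effects
are recovered and localized — not that effect sizes transfer to real
cohorts.

## Saliency

Grad-CAM++ attributes a class score to image regions: with A the
post-activation feature maps of the last conv layer and g = ∂S/∂A the
gradient of the linear (pre-softmax) class score, the channel weights are
Σ α·relu(g) with α = g² / (2g² + g³·ΣA), and the map is relu(Σ w·A),
bilinearly upsampled to input resolution. Class-level maps average the raw
per-sample maps over all test samples of a class, then max-normalize
(normalizing before averaging is available as an option). Class-level maps
attend to everything the network uses, including anatomy shared by both
classes; the *absolute difference* of the two class maps isolates the
discriminative region, and that is what the localization checks assert on
(planted-blob mass fraction ≈ 3× its area fraction in tests). At 64×64
input the last conv maps are 6×6, so localization is coarse; below ~32×32
input it is not meaningful (2×2 maps).

## Numerical and procedural choices

- Exact conditional HWE test (enumeration over heterozygote counts in
  log-space), matching standard GWAS QC; χ² variant as option. QC
  comparisons are strict (<), rules checked in order non-autosome → call
  rate → MAF → HWE, first failure reported.
- Middle slice = index ⌊dim/2⌋; canonical axis convention x = sagittal,
  y = coronal, z = axial; NIfTI volumes reoriented to canonical on load.
- Min-max normalization per image; constant images map to zeros.
- Welch t-test by default everywhere (pooled-variance exposed); both
  constant samples with equal means → p = 1 with a degenerate flag.
- Ranking ties broken by lexicographically smaller SNP id.
- Sub-seeds derived via CRC32 of (seed, purpose, identifiers), keeping all
  runs reproducible from one integer and independent across SNPs/reps.
- Scan tables are written row-by-row and reloaded on restart; completed
  (SNP, plane) pairs are not recomputed.

## Problem sizes used in validation

Cohort checks run at 120–200 subjects, 10–300 SNPs and 32³–64³ volumes;
fine-tuning calibration uses 40 null SNPs at 5+5 retrains; the simulation
grid is 10 mean-shift × 3 sample-size × 3 proportion cells with 3
replicates. These sizes were chosen so the whole validation suite runs on
one CPU in minutes while keeping every statistical check adequately
powered.

## Known limitations

- The CNN is numpy-based and single-threaded; genome-scale scans should
  use the linear stand-in, reserving the CNN for top-ranked SNPs and
  saliency.
- The fine-tuning t-test treats retrain values as independent; with a
  deterministic classifier and no subsampling it is anti-conservative (see
  above).
- Dominant/recessive pooling only; no additive three-class mode.
- No covariate adjustment, population-structure correction or genome-wide
  significance thresholds: ranking and the permutation contrast are the
  inferential tools.
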