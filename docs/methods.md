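# Methods

`twinconn` re-implements, as a tested and reusable pipeline, a
resting-state connectomics analysis of a three-group cohort of female
monozygotic twins — healthy control twins (HC), unaffected co-twins
(COTWIN) and twins with first-episode schizophrenia (SZ), 20 subjects
per group.  Because the original fMRI data are private, every stage is
validated end to end on a synthetic cohort generator that plants known
group differences.  This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic validation does
and does not establish about real data.

## Signal model and cleaning

A subject's input is a regions × time matrix of BOLD signals (or a 4-D
voxel volume plus an integer-labelled atlas, averaged per region), at
TR = 2 s with 180 volumes.  Cleaning follows the order

1. discard the first `n_discard = 10` volumes (signal equilibration;
   180 → 170),
2. optional motion-based exclusion: a subject is dropped if any volume
   exceeds 2 mm translation in any axis or 2° rotation about any axis
   (*strict* inequalities — a trace touching exactly 2.0 is kept),
3. nuisance regression on an intercept plus user-supplied covariates
   (the 24-parameter motion expansion {p, p lagged one volume, p²,
   (p lagged)²} of the six rigid-body parameters, plus white-matter,
   CSF and global signals where available),
4. band-pass 0.01–0.1 Hz,
5. linear detrending.

The ordering regression → filter → detrend is a convention of this
package; the steps are individually idempotent linear projections and
filters, and regressing twice with the same covariates is a no-op.  The
band-pass is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`): zero phase, so no temporal shift leaks into the lagged
regressions downstream.  The attenuation contract (≥ 20 dB one octave
beyond either edge, in-band amplitude within 5 %) refers to the
steady-state response; the first/last ≈ 50 samples carry boundary
transients of the two-pass filter.  Slice timing, realignment, spatial
normalization and smoothing are out of scope (assumed done upstream by
standard tools).

## Connectivity

**Effective connectivity (EC)** for the ordered pair x → y is the signed
coefficient *b* in the bivariate lag-1 regression

    y_t = c + a·y_{t−1} + b·x_{t−1} + e_t ,   t = 2…T,

after z-scoring both series.  The signed coefficient — not an F
statistic or a log-variance ratio — is used because the group analyses
depend on the *direction* of the coupling (edges that are positive in
controls and negative in patients).  Standardization makes coefficients
comparable across subjects; the sign is invariant to rescaling either
way.  A whole-brain EC network computes all R(R−1) ordered pairs (at the
full 272-region parcellation, 73,712 edges); each entry depends only on
the two regions involved.  Exactly collinear pairs (e.g. duplicated
regions) are masked as missing with a logged warning.

**Functional connectivity (FC)** is the zero-lag Pearson correlation.
Group statistics on FC operate on Fisher-z values (`atanh r`), the
standard variance stabilization; reported group means can be
back-transformed.

Edge vectors are laid out row-major with the diagonal skipped
(directed, length R(R−1)) or over the upper triangle (undirected,
R(R−1)/2), with an index mapping positions to region-label pairs.

## Permutation inference

Both tests control family-wise error by comparing each edge's t
statistic to the permutation null of the **maximum |t| over all edges**:

* *one-sample presence test*: each permutation draws one ±1 sign per
  subject and applies it to that subject's entire edge vector.  Sharing
  the sign vector across edges preserves the cross-edge dependence and
  is what makes the max-statistic null valid family-wise.
* *two-sample difference test*: each permutation reassigns subjects to
  the two groups with group sizes preserved; t is the pooled-variance
  two-sample statistic.

The corrected p of an edge is the fraction of the `n_perm = 1000` null
maxima that are ≥ its true |t| (ties count; a tiny relative tolerance,
1e-10, makes exact ties robust to floating-point jitter — without it the
complement relabelling, which ties the observed statistic exactly, can
be dropped).  p = 0 means "below 1/n_perm" and is reported as
p < 1/n_perm.  Random permutations are simple Monte-Carlo draws (repeats
allowed); exhaustive enumeration of all sign assignments / relabellings
is available for small n and is used to validate the Monte-Carlo path.
The two-sample test canonicalizes the group pair internally (sorted
labels, sign flipped on output), so swapping the groups flips every sign
and leaves every p bit-identical.

Subjects are treated as exchangeable.  Twin-pair dependence is ignored,
mirroring the emulated design — a statistical caveat, not an endorsement:
with paired subjects the two-sample relabelling null is anti-conservative
in principle.

## Multivariate pattern analysis

Linear soft-margin SVM (C = 1) on whole-brain EC, FC (Fisher z) or
concatenated edge vectors, under leave-one-out cross-validation.
Features are z-scored with training-fold statistics only; a
training-fold-constant feature is centred to zero.  Significance:
the entire LOOCV is re-run under `n_perm` label permutations (class
sizes preserved) and p is the fraction of chance accuracies ≥ the true
accuracy.  The mean signed weight vector over folds quantifies each
edge's contribution; the top ⌈1 %⌉ of |weights| (ties broken by fixed
edge order) are compared against the univariately significant edge set.
One-vs-rest classification pools the remaining groups into a single
"rest" class.  No kernel search, no hyperparameter tuning, no feature
selection inside folds: the whole-brain pattern is the feature set.

**Finite-sample chance level.**  The expected LOOCV accuracy of this
procedure on label-independent features is *slightly below* one half:
holding a subject out leaves its class with one fewer training example,
and the max-margin solution leans toward the majority class (with more
features than subjects the training folds are separable, so per-class
cost reweighting cannot correct this).  We measured 0.44–0.49 across
16–40 subjects and 3–200 features, e.g. 0.4835 ± 0.0007 at 40 subjects
and 30 features.  The permutation test is the correct calibration in
exactly this situation: the null accuracies carry the same bias, the
true accuracy is exchangeable with them under label independence, and
the resulting p values are (conservatively, because accuracy is
discrete) uniform — we measure the fraction of null experiments with
p < .05 at ≈ 0.035 against the nominal 0.05.  Chance-level checks in the
test suite therefore compare against the permutation-null mean, not
against the nominal 0.5, with a loose absolute band guarding the size of
the bias.

## Synthetic cohort generator

Subject series are drawn from a stationary first-order vector
autoregression x_t = Aᵀ x_{t−1} + ε_t, ε_t ~ N(0, Σ) (A is oriented
rows = source, columns = target).  Defaults emulate the study
conditions: 272 regions (configurable; scaled-down runs use 20–71),
180 volumes at TR = 2 s, three groups of 20.  The base dynamics are a
uniform self-coupling of 0.25 with unit innovation covariance — weakly
autocorrelated, mutually independent regions.  Group effects are sparse
overrides: additive directed coupling weights (picked up by the Granger
stage; default planted effect +0.4 on nine disjoint source→target pairs
for the SZ group) and additive innovation covariances (picked up by the
Pearson stage; +0.3 on a disjoint set of pairs), so directed and
undirected alterations are disjoint by construction.  Between-subject
heterogeneity is N(0, 0.05²) jitter on the planted couplings only,
keeping stationarity checks cheap and effects interpretable.  Every
per-subject coupling matrix is verified to have spectral radius < 1;
non-stationary specs are rejected.  A burn-in of 200 steps is discarded
(at spectral radius ≤ 0.9 the start-state influence is < 1e-9).
Per-subject randomness fans out from the master seed through
`SeedSequence([seed, subject_index])`, so cohorts are reproducible and
subjects independent.

The planted +0.4 coupling yields a between-group two-sample t of ≈ 10–12
on the standardized bivariate coefficient at n = 20 per group and
T = 170 — comfortably above the max-|t| significance threshold (≈ 4.5 at
380 edges), which is what makes the 9/9-sensitivity check stable.  Note
the bivariate estimate targets the large-T regression coefficient of the
generative model, which differs from the planted weight when confounding
paths exist; validation oracles therefore compare against a long-series
OLS fit, not against the planted number.

What the generator does *not* emulate: hemodynamic convolution,
physiological noise, scanner drift, spatial autocorrelation of voxel
noise, or twin-pair correlation.  Passing tests demonstrate the
correctness and calibration of the estimators and permutation procedures
under a known ground truth — they do not certify effect sizes,
sensitivity or specificity on real BOLD data.

## Clinical statistics

One-way ANOVA F across the three groups and pooled-variance (Student)
two-sample t between the twin groups, computable from raw scores or from
printed summaries (mean, sample SD, n).  The summary-path F uses the
size-weighted grand mean, MSB = Σ nᵢ(mᵢ−m̄)²/(k−1) and
MSW = Σ (nᵢ−1)sdᵢ²/Σ(nᵢ−1); treating published SDs as sample (n−1) SDs
and t as pooled reproduces every printed statistic of the emulated
cohort's demographic table to ±0.01 (age F 0.866 … GAF F 34.07, PANSS
t −21.13).  The two paths agree to 1e-8 when summaries come from the
same data, and F = t² for two groups.

## Problem sizes in the validation suite

Simulation scales are package choices made once: FWE calibration uses
500 null cohorts of 200 edges with n_perm = 1000 (measured FWE ≈ 0.04–
0.05); planted-edge recovery uses R = 20 (380 directed edges — nine
strictly disjoint planted pairs need 18 regions; chained layouts would
create confounded bivariate paths) over 50 seeds; MVPA calibration uses
200 null experiments of 16 subjects × 10 features with n_perm = 100
(the low-dimensional regime keeps the LOOCV bias small while leaving
the p calibration intact).  The full-parcellation edge-count check runs
one subject at R = 272, T = 170 (73,712 bivariate fits, a few seconds).

## Known limitations

* Twin-pair dependence is ignored throughout (matching the emulated
  procedure); a pair-aware permutation scheme would be the principled
  extension.
* The bivariate Granger coefficient is not a conditional (multivariate)
  causal estimate; indirect paths induce biased edge weights by design.
* LOOCV accuracy is pessimistically biased at chance and has high
  variance; permutation p values, not raw accuracies, are the calibrated
  quantity.
* p values can be exactly 0 at Monte-Carlo resolution and are then only
  bounded (p < 1/n_perm).
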