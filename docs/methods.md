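# Methods

## Overview

`fcstage` implements a group-level analysis of seed-based resting-state
functional connectivity (rs-FC) for a two-stage, within-participant
design: every participant is scanned before and after an intervention,
and the question is whether — and through which connections — the two
stages can be told apart. Each scan is reduced to the Pearson
correlation matrix of its seed time series; the C(S, 2) unique
off-diagonal coefficients form the scan's FC feature vector. A robust
screen and a univariate paired test select candidate connections, PCA
compresses them into a handful of uncorrelated component scores, and a
linear soft-margin SVM classifies each scan as pre- or post-stage under
leave-one-participant-out cross-validation (LOOCV). The fitted PCA
loadings (optionally combined with the SVM weights) are finally
back-projected to score individual connections, seeds and networks.

## Feature chain

Given stage matrices `X_pre`, `X_post` (participants × connections):

1. **Outlier screen.** For every feature and stage independently, a
   value is an outlier if it lies more than 3 scaled MADs from the
   feature median, where the scaled MAD is `1.4826 · median|x − median|`
   (the 1.4826 constant makes the MAD a consistent estimate of the
   standard deviation under normality). A feature containing any
   outlier in either stage is dropped from both. When the MAD is zero
   (at least half the values tied at the median), any value off the
   median is flagged — the strict reading of the rule. Note the rule is
   intentionally robust, not calibrated: on clean Gaussian features with
   20 participants it already flags roughly one feature in five per
   stage, because the sample MAD at n = 20 is a noisy spread estimate.
   Removing about a third of all features on clean data is therefore
   expected behavior at this sample size, not a defect.
2. **Normality filter.** The paired differences (post − pre) of each
   surviving feature are standardized and tested against a standard
   normal with the classical two-sided Kolmogorov–Smirnov test (exact
   null distribution; no Lilliefors correction). Features rejected at
   `alpha_ks = 0.05` are excluded before the t-test. Testing the
   differences (rather than each stage separately) is the variant that
   matches the quantity the subsequent paired test actually assumes
   normal; per-stage testing is available via the same function.
3. **Selection.** A two-sided paired t-test per feature
   (`t = mean(d) / (sd(d)/√n)`, df = n − 1); features with p < `alpha`
   (default 0.05, no multiplicity correction by default; an optional
   Benjamini–Hochberg flag exists) are selected. Features with
   zero-variance differences get p = 1 with a warning. If nothing
   passes — possible in effect-free training folds — the single
   smallest-p feature is kept with a warning so downstream stages and
   CV folds remain well defined.
4. **PCA.** The selected columns of both stages are stacked
   (2n × p_sel), mean-centered — variances are deliberately *not*
   standardized, since the features share the correlation scale and
   rescaling would distort the covariance structure — and decomposed by
   full SVD. At most `min(2n − 1, p_sel)` positive-variance components
   exist; the kept count k is the smallest whose cumulative explained
   variance strictly exceeds `variance_threshold` (default 0.85).
5. **Score standardization.** Each kept component score is centered and
   scaled to unit standard deviation using training statistics only, so
   no component dominates the SVM through sheer variance.

All masks are stored in original feature indexing, so any selected
feature maps back to its seed pair through the package-wide FC index
convention (row-lexicographic over pairs i < j, 0-based).

## Classification and validation

The classifier is a binary linear-kernel soft-margin SVM with two
hyperparameters: the misclassification cost (box constraint C) and a
kernel scale that divides the feature vectors before the inner product.
"Pre" is the positive class (so sensitivity is the pre-stage recall);
a decision value of exactly zero predicts "post".

Cross-validation is leave-one-participant-out: each fold holds out both
scans of one participant, preventing a subject's correlated pre/post
pair from straddling the split. Two protocols are exposed:

- **pooled** — the feature chain is fitted once on the full
  cohort, then only the SVM is refit per fold. This mirrors the common
  published protocol but lets the held-out participant inform outlier
  screening, selection and PCA.
- **nested** — the entire chain is refit inside every training fold.
  Nothing about the held-out participant touches any fitted artifact.

On effect-free cohorts the nested protocol centers on chance (50%)
while the pooled fit typically reaches ~80% — a direct measurement of
selection leakage, reproduced by the test suite and the acceptance
script. The nested protocol is the honest generalization estimate; the
pooled protocol is retained because quantifying its bias is part of the
analysis.

Hyperparameters can be tuned by Bayesian optimization of the LOOCV
error over the log10 box `[1e−3, 1e3]²`: a Gaussian-process surrogate
(Matérn ν = 2.5) with expected-improvement proposals, 5 uniform warm
starts, 30 evaluations total, fully deterministic under the seed. The
returned point is the best observed, and the whole trace is reported.

Metrics: accuracy, sensitivity, specificity from the pooled 2×2
confusion matrix; AUC by the trapezoidal rule over the pooled decision
values (0.5 when all decisions tie).

## Attribution

Two connection-weighting modes. The default scores each selected
connection by the mean absolute PCA loading across the kept components
(a property of the learned feature space); the alternative
back-projects the SVM weights through the loadings,
`|Σ_c w_c · loading_fc|` (a property of the decision rule). Seed
weights use the half-split rule: each connection donates half its
aggregate weight to each endpoint, and a seed's cumulative weight is
the mean of its received half-weights, so summed seed weights conserve
the total connection weight. Connections are partitioned into
strengthened/weakened by the sign of the group-mean change (post − pre)
on the signed correlation scale (a magnitude-based variant is
flag-gated), and into motor/non-motor by whether at least one endpoint
lies in a motor network (default motor set: the two somatomotor
networks, hand and mouth; a both-endpoints-motor connection counts once
as motor). Network involvement counts, per network, the selected
connections touching it (a within-network connection counts twice), and
the normalized variant divides by the network's seed count.

## Synthetic cohort generator

The generator emulates the study conditions at desk scale: 20
participants × 2 stages of T = 231 time points at TR = 2.6 s,
band-limited to 0.01–0.1 Hz. Per stage it builds a latent correlation
matrix with network-block structure (within-network baseline 0.3,
between-network 0.1, unit diagonal); the post matrix differs from the
pre matrix by `effect_size` (default +0.4) on `n_planted` randomly
chosen pairs. Planted pairs are drawn seed-disjoint from the
between-network pool when possible: the perturbation then has
eigenvalues exactly ±effect, so positive-definiteness of both matrices
is guaranteed rather than hoped for; both are verified SPD regardless.
Series are white Gaussian noise passed through a 4th-order Butterworth
band-pass (applied forward-backward; 128 burn-in samples trimmed per
end), standardized, and mixed by the Cholesky factor of the stage
matrix — the simplest stationary process whose sample FC converges to
the latent correlations as T grows, which the tests verify at
T ∈ {100, 1000, 5000}. Optional corruption replaces a fraction
`outlier_rate` of FC entries with ±0.999 (far outside the sampling
spread of any smooth feature) and logs every injected entry.

Defaults worth noting:

| parameter | default | rationale |
|---|---|---|
| `n_participants` | 20 | study cohort size |
| `n_timepoints`, `tr_seconds` | 231, 2.6 s | study acquisition |
| `band_hz` | 0.01–0.1 Hz | BOLD fluctuation band |
| `n_seeds` | 30 | keeps C(S,2) = 435 tractable; 236 supported |
| `n_planted`, `effect_size` | 12, +0.4 | moderate planted signal, well inside (−1, 1) |
| `base_within` / `base_between` | 0.3 / 0.1 | within-network coupling above between |
| `noise_sd` | 0 | additive white observation noise attenuates sample correlations away from the latent targets, breaking the generator's own consistency contract; kept as an explicit robustness knob |
| `outlier_rate` | 0 | injection is opt-in; the analysis drivers use 0.002, at which the screen's total attrition (~38%) matches the scale observed on real cohorts of this size |

What the generator does **not** emulate: hemodynamics, head motion,
scanner drift and physiological noise, lesion anatomy, inter-individual
covariance heterogeneity, and spatial autocorrelation tied to real seed
geometry. Passing tests therefore demonstrate the statistical machinery
— calibration, leakage, recovery of planted effects, conservation laws
— not performance on real scans.

## Numerical choices and degenerate inputs

- Correlation matrices are symmetrized, clipped to [−1, 1], and given
  an exact unit diagonal; constant series columns are an error naming
  the seed (a silent NaN feature would corrupt the outlier screen).
- Vectorization requires symmetry within 1e−8; the index map is exact
  integer arithmetic (searchsorted over row offsets).
- The KS filter is computed vectorized (sorted ECDF distance +
  `kstwo` exact tail); the suite pins it to `scipy.stats.kstest`
  feature by feature. Constant columns are detected by zero range, not
  floating-point sd.
- PCA positive-variance components are counted above 1e−12 of relative
  variance; reconstruction with all components is verified to 1e−8.
- Fisher z is available but off by default (the SVM makes no normality
  assumption on its inputs); |r| = 1 errors unless clamped.
- The SVM is solved by libsvm (tolerance 1e−6); the kernel-scale
  contract `train(X, scale=s) ≡ train(X/s, scale=1)` is tested.
- Exact-tie group-mean changes (impossible for continuous data) are
  classified weakened with a warning; a zero decision value predicts
  "post".

## Problem sizes

Tests and the acceptance script run the full method at 30 seeds
(435 connections), 20 participants, T = 231 — small enough for the
whole suite to complete in well under a minute while keeping every
statistical check at the study's sample size. Null-calibration and
leakage measurements use 20 independent replicate cohorts; the nested
null accuracy is checked against a conservative 95% band around 0.5
(binomial at the 400-participant-fold level, treating folds as the
independent unit within replicates). The packaged 236-seed template is
exercised for atlas and combinatorial checks; running the full pipeline
at 236 seeds (27,730 connections) is supported but not required by the
tests.

## Known limitations

- The packaged default atlas carries synthetic placeholder coordinates
  (the original coordinate list is not redistributed); network
  memberships and counts are faithful, and no computation reads
  coordinates except the visualization exports.
- The exact selection threshold that produced a given published feature
  count cannot be recovered without the original scan data; `alpha` is
  exposed instead.
- Bayesian optimization on near-separable cohorts has a flat objective
  (many hyperparameter points reach zero CV error), so the returned
  optimum is one of many equivalent points; the best-observed contract
  and reproducibility under seed are what the package guarantees.
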