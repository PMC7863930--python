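# Methods

`mirdiag` implements a serum-miRNA biomarker discovery and diagnosis
workflow for case-control cohorts: univariate logistic differential
expression with false-discovery-rate control, stability voting built on a
SCAD-penalized sparse SVM, an RBF-kernel SVM diagnostic model tuned by
double (nested) cross-validation, external-cohort validation against a
scalar tumor-marker rule, and PCA views with confidence ellipses.  This
note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic-cohort experiments do and do not
demonstrate.

## Input model

The pipeline consumes a normalized, log2-transformed expression matrix
(features x samples; serum miRNA microarray intensities in the motivating
application) and a per-sample metadata table carrying a disease subgroup
(PC = pancreatic cancer case; ICC, SC, CRC, GIST = other cancers; Ch, N =
benign/healthy), a cohort assignment (training or validation), and an
optional scalar comparator biomarker (a CA19-9 analogue, U/mL).  Two
control definitions are first-class: case vs every non-case sample
("non-PC"), used to build the diagnostic model so that the panel is
specific to the case disease rather than to cancer in general, and case
vs non-cancer only, used for the secondary differential-expression
comparison and the Venn partition of the final panel.

## Differential expression

Each feature is screened marginally with a logistic regression of the
binary label on that feature's log2 intensity (intercept included, no
covariates).  The slope test is a likelihood-ratio test by default.  The
Wald test is available (`statistic="wald"`) but is *not* the default
because of the Hauck–Donner effect: near separation the Wald standard
error grows faster than the estimate, so the strongest markers —
precisely the ones a screen must keep — receive large p-values.  In a
direct experiment, a single 3-SD marker at n = 40/40 received a Wald p of
0.069 and failed the screen in a third of folds, while its
likelihood-ratio p is astronomically small.  Features whose Newton
iteration is still moving at the iteration cap (quasi-separation, where
the MLE diverges) fall back to the two-sided Mann–Whitney rank-test
p-value, which keeps the voting loop crash-free and the p-value on a
defensible scale.  Family-wise adjustment is Benjamini–Hochberg
(`statsmodels.stats.multitest`), significance at adjusted p < 0.05.
Per-marker AUC is the normalized Mann–Whitney U (ties counted 1/2),
reported oriented (>= 0.5) with the orientation sign retained.

The per-feature fits are Newton iterations vectorized across features
(two parameters each), so screening a few thousand features inside every
cross-validation fold costs milliseconds.

## SCAD-penalized sparse SVM

The selection stage fits a linear classifier minimizing

    (1/n) * sum_i loss(y_i (w·x_i + b)) + sum_j p_lambda(w_j)

with the smoothly clipped absolute deviation penalty

    p(t) = lambda |t|                                   |t| <= lambda
         = -(t^2 - 2 a lambda |t| + lambda^2)/(2(a-1))  lambda < |t| <= a lambda
         = (a+1) lambda^2 / 2                           |t| > a lambda

with a = 3.7 (Fan & Li's recommendation).  The penalty is continuous
(value lambda^2 at the first knot), even, non-decreasing in |t| and
constant beyond a·lambda, so large coefficients are nearly unbiased while
small ones are thresholded to exact zero — the property that motivates
SCAD over the lasso for support recovery.

**Surrogate loss.** The default per-sample loss is the least-squares
margin loss (1 - y f)^2 (the LS-SVM / proximal-SVM surrogate).  The
clipped squared hinge max(0, 1 - y f)^2 is available, but it interacts
badly with penalty-based tuning: on separable data (routine at these
sample sizes once a couple of strong markers are present) SCAD's flat
tail lets weights grow at no cost, the clipped loss reaches exactly zero
for *any* support that separates, and every goodness-of-fit tuning
statistic degenerates.  The LS surrogate penalizes over-margin fits, so
its minimized value stays informative; it is also the fixed point toward
which the successive quadratic approximations used by hinge-loss SCAD-SVM
solvers iterate.

**Solver.** Local quadratic approximation: around the current iterate the
penalty on each coefficient is majorized by a quadratic with curvature
p'(|w_j|)/(|w_j| + eps) (eps = 1e-8), giving a ridge-type Newton system
(intercept unpenalized); the step is damped by backtracking on the exact
objective, so the recorded objective sequence is non-increasing by
construction.  Coefficients below `zero_threshold = 1e-4` (on the
standardized scale) are zeroed whenever that does not increase the
objective, and the final support is the set of exactly nonzero weights.
Initialization is the deterministic ridge solution (ridge strength 0.1),
which removes run-to-run variability from the non-convex objective; a
warm start from the neighbouring lambda on the tuning path can be enabled
but is off by default, because LQA cannot revive a zeroed coefficient and
warm starts from sparser solutions therefore rarely help.  Convergence is
max |delta w| < 1e-6 within 200 iterations.  Features are standardized
with training statistics; reported weights are mapped back to the raw
scale, making the fit equivariant under feature rescaling.

**Tuning.** lambda is selected on a 20-point log-spaced grid spanning
[0.01, 2] (standardized data; bracketing the intercept-only and
near-unpenalized regimes) by an approximate generalized cross-validation
statistic

    GCV(lambda) = total loss / (n (1 - c·df/n)^2),  df = |support| + 1.

The degrees-of-freedom weight c defaults to log(n)/2.  The classical
c = 1 statistic behaves like AIC: each pure-noise feature enters with
probability P(chi2_1 > 2) ≈ 0.16, which at p = 20 yields ~3 expected
false positives and destroys support recovery.  The log(n)/2 calibration
makes the criterion BIC-equivalent and the tuned estimator
selection-consistent — the oracle property that is the stated reason for
using SCAD in the first place.  Ties (and near-ties within 1e-12)
resolve to the larger lambda, i.e. the sparser model.  Grid points where
c·df >= n are skipped; if none remain the grid is rejected as too small.

Measured under the fixed benchmark conditions (n = 100, p = 20, two
informative features at 2 SD): exact-support recovery (both true features,
<= 2 false positives) in 96% of 50 replicates; on pure noise the selected
lambda lies in the upper half of the grid in 100% of replicates with
support size <= 2 in 98%.

## Stability voting

The training cohort is split into 5 class-stratified folds (fold sizes
and per-class counts differ by at most one; `StratifiedKFold` with a
seeded shuffle); each fold's *training* portion undergoes the FDR screen
followed by the GCV-tuned SCAD-SVM, and the nonzero-coefficient features
form one candidate set.  With the default 200 repetitions this yields
1000 candidate sets; a feature's selection count is its voting score.
Ranks are by count, ties broken by full-training-cohort univariate AUC
and then lexicographically, so the ranking is total and deterministic.
Both selection stages are recomputed inside every fold — the held-out
fold never touches the screen, the standardization, or the SVM — which
the test suite verifies with a perturbation probe.  An empty FDR pass
yields an empty candidate set without an SVM fit; failed fits are logged
and counted as empty rather than retried, keeping the denominator of the
selection frequency exact.

## Diagnostic model and double cross-validation

The diagnosis stage builds an RBF-kernel soft-margin SVM on the top-K
ranked markers (standardized with training statistics).  Hyperparameters
come from an exhaustive grid — gamma in 2^-10 … 2^10 (21 values), cost in
2^-7 … 2^7 (15 values) — scored by mean inner 5-fold cross-validated
AUC.  AUC saturates at 1 over
large grid regions on well-separated data, so exact ties are routine; they
resolve by mean inner-CV *accuracy* first, then smaller cost, then
smaller gamma.  The accuracy tie-break matters: AUC is insensitive to the
decision intercept, and the most-regularized corner of the grid produces
near-zero decision values with essentially arbitrary intercepts (the
libsvm offset is under-determined when every dual variable is at its
bound), which would poison both thresholded metrics and probability
calibration if selected.

Panel size K is chosen by outer 5-fold cross-validation repeated over
reseeded partitions (20 by default): for every repeat, outer fold and K,
hyperparameters are tuned on the outer-training part only, a Platt
sigmoid P(case|f) = 1/(1 + exp(A f + B)) is fitted on that pair's
out-of-fold decision values (smoothed targets; damped-Newton on the
convex cross-entropy, matching sklearn's sigmoid calibration to 1e-5),
and the untouched outer-test fold is scored.  AUC is threshold-free;
sensitivity and specificity use the configured probability cutoff (0.5
before threshold selection).  Accuracy is defined as (sensitivity +
specificity)/2 throughout.  K* is the smallest K whose mean AUC is within
epsilon = 0.005 of the maximum (the saturation point of the performance
curve); the probability threshold is then chosen among {0.5, 0.55, 0.6,
0.65, 0.7} by balanced accuracy on the pooled out-of-fold probabilities
at K*, ties resolving toward 0.5.

Two ranking modes exist for the double CV.  The default (`"given"`) reuses
the single ranking computed on the whole training cohort — the way a
fixed, published marker ranking is evaluated in practice; this carries a
mild selection bias because the ranking saw the outer-test samples.  The leakage-free mode (`"refit"`) recomputes
the voting ranking inside every outer-training part (padded by
outer-training univariate AUC when voting selects fewer than K markers);
it is the mode under which the permuted-label null calibration is
verified (mean test AUC within [0.40, 0.60] for every K), at roughly the
cost of one voting run per outer fold.

The final model is refit on the whole training cohort at (gamma, cost)
tuned on it, with Platt calibration on 5-fold cross-validated decision
values.  The model object stores support vectors, dual coefficients,
kernel width, standardization and calibration parameters explicitly, so
prediction is plain numpy and JSON serialization round-trips to machine
precision.

External validation requires sample ids disjoint from training (a
leakage guard), reports per-sample probabilities, the confusion table at
the stored threshold, AUC, and a pointwise 95% ROC confidence band from a
class-stratified percentile bootstrap (2000 resamples, TPR interpolated
on a common FPR grid).  The comparator diagnosis applies the scalar rule
value > cutoff (default 37, the conventional CA19-9 positivity cutoff in
U/mL), with AUC computed from the raw continuous value; missing
comparator values count as negative calls and are excluded from the AUC.

## PCA views

Principal components are fitted on the training cohort over a chosen
feature subset (all features, or the differentially expressed set) via
SVD of the centered, unit-scaled data (serum intensities span very
different ranges; scaling is the default but optional).  Loading signs
are fixed so each component's largest-magnitude entry is positive.
Validation samples are *projected* with the frozen training centers,
scales and loadings — never refit.  Group scatter in the first two
components is summarized by a confidence ellipse: center at the group
mean, shape = sample covariance x 2 F^{-1}(level; 2, df), the radial
quantile of a bivariate t distribution with df = n - 1 (configurable; the
choice of df follows the common plotting convention and converges to the
chi-square radius for large groups).  Coverage is verified by simulation:
draws from the matched bivariate t law fall inside the 95% ellipse at
0.95 +/- 0.02 over 10,000 points.

## Synthetic cohorts

The generator emulates a serum-miRNA case-control dataset on the log2
scale: 2578
features by default, a 63 case / 63 control training cohort and a 25
case / 81 control validation cohort, Gaussian per-feature noise (SD 1.0,
a typical log2-scale array dispersion), an informative subset with signed
additive mean shifts in cases, optional equicorrelated feature blocks
(single rho per contiguous block — the simplest structure that stresses
the selector with redundant features), and training-control subgroups
drawn proportionally to a realistic mixed control-arm composition
(other cancers, benign disease, healthy subjects) with
validation controls from the hard tumor subgroup.  "Strong" markers in
the test scenarios carry 2-SD shifts, the magnitude at which the support
recovery experiment is defined.  An optional fraction of the case shift
can be applied to validation controls to mimic partial molecular overlap
between the case disease and the validation-control disease; the default
is 0.  The comparator generator draws log-normal values parameterized by
(median, log-SD) per arm; defaults in the acceptance workflow use medians typical of a
tumor-bearing validation cohort (about 197 U/mL for cases, 46 U/mL for
controls), whose heavy overlap is what
makes the scalar rule weak against the expression panel.

What passing these tests shows — and does not.  The synthetic law is
Gaussian with location shifts and at most block-equicorrelated noise; real
serum profiles have heavier tails, batch structure, correlated noise
across arbitrary feature sets, and effect sizes that vary by marker.
Recovery and AUC figures on the synthetic cohorts therefore demonstrate
the *internal correctness* of the pipeline (no leakage, correct
statistics, selection behaving as theory predicts under its assumptions),
not expected performance on clinical data.

## Problem sizes in the routine checks

The automated experiments run at reduced scale chosen to exercise every
code path with stable statistics: voting fidelity at p = 300 features
with 5-fold x 20 repeats over 10 cohort seeds; null calibration with 3
double-CV repeats and K = 2…20; the end-to-end analogue at p = 500 with
15 informative markers, 5-fold x 20 voting and 2 double-CV repeats over
K in {5, 10, 15, 20}.  All randomness descends from a single root seed
through named substreams, and an end-to-end determinism check asserts
byte-identical artifacts across reruns.

## Known limitations

- The LQA solver cannot re-activate a coefficient once zeroed within a
  single fit; the ridge initialization avoids starting at zero, but the
  solver remains a local method on a non-convex objective.
- GCV's degrees-of-freedom weight log(n)/2 is a calibration, not an
  estimate; c = 1 restores the classical statistic.
- Platt calibration on pooled cross-validated decision values assumes the
  per-fold decision scales are comparable; the accuracy tie-break in the
  grid search avoids the degenerate hyperparameters for which they are
  not.
- The bootstrap ROC band is pointwise, not simultaneous.
- With fewer ever-selected markers than the requested K range, the
  pipeline truncates the range (and the refit ranking mode pads by
  univariate AUC); both are logged.
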