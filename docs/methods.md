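# Methods

This note documents the models and procedures implemented in `cgmrisk`,
the calibration of the synthetic cohort generator, the numerical choices
that matter, and what the package's passing tests do and do not show
about real data.

## Range metrics

A record is a timestamped interstitial glucose series on a nominal
5-minute grid, clamped to the device reporting range [40, 400] mg/dL.
A calendar day (local midnight boundaries, no timezone arithmetic) is
*complete* when it holds at least `completeness_fraction × 288` valid
readings; the default 0.8 (≥ 231 readings) follows CGM consensus
practice, and is configurable because the underlying study protocols
rarely state a rule. Analysis retains complete days only; subjects need
at least two to be eligible. Within retained days, every reading
carries equal weight — on a uniform grid, sample proportions equal time
proportions — and gaps are ignored rather than interpolated.

Boundary convention: readings of exactly 70 or 140 mg/dL are *in
range*; TAR and TBR are the strict inequalities (> 140, < 70). TIR,
TAR and TBR therefore partition the retained readings and sum to 100%.

## Glucodensities and Wasserstein geometry

Each subject's glucodensity is a Gaussian kernel density estimate of
their glucose readings on a fixed grid over [40, 400] mg/dL (default
step 1 mg/dL), with boundary reflection at both support ends and
renormalisation to unit trapezoidal integral. The bandwidth follows
Silverman's robust rule, `0.9·min(SD, IQR/1.34)·n^(−1/5)`; a degenerate
(single-valued) record falls back to a 1 mg/dL minimum bandwidth with a
warning.

Distances use the quantile representation: the 2-Wasserstein distance
between 1-D distributions is the L2 distance between quantile
functions, evaluated on a uniform midpoint probability grid (default
512 points). The barycenter (Fréchet mean) averages quantile functions
pointwise and maps the result back to a density on the grid; every
subject carries equal weight regardless of wear time, because subjects,
not readings, are the analysis unit.

The group-difference test is a permutation test: statistic = squared
W₂ distance between the two group barycenters; the null is built by
relabelling subjects with group sizes preserved; the p-value uses the
add-one rule `(1 + #{perm ≥ obs}) / (1 + B)`, so it is never zero.
No claim is made that this is the test behind any particular published
p-value — distributional analyses in the literature rarely state their
null scheme — so the test is validated by its type-I error rate
(rejection rate ≈ α when both groups come from one generator), not by
reproducing a printed p.

## Clinical criteria

All cut-offs are implemented with their conventional strict/inclusive
comparisons: ADA thresholds FPG ≥ 126 mg/dL, HbA1c ≥ 6.5% (diagnosis
additionally requires a second abnormal sample unless hyperglycaemia is
unequivocal); ATP-III components waist > 102/88 cm (M/F),
triglycerides ≥ 150 mg/dL, HDL < 40/50 mg/dL (M/F), blood pressure
≥ 130 or ≥ 85 mmHg or antihypertensive use, fasting glucose
≥ 110 mg/dL or antidiabetic therapy; syndrome at ≥ 3 components.
Glucose unit conversion uses 18.0 mg/dL per mmol/L. The NGSP→IFCC
HbA1c conversion is the master equation (x − 2.15) × 10.929, reported
to one decimal. Incident T2D over follow-up is ADA-positive labs *or*
a physician record of diabetes.

## Incidence and the prediction model

Cumulative incidence is events / at-risk over the fixed 5-year horizon.
Rates use exact (Garwood) Poisson intervals:
`lo = χ²(α/2, 2k)/(2T)`, `hi = χ²(1−α/2, 2k+2)/(2T)` with T in
thousands of person-years and lo = 0 at k = 0. For synthetic cohorts,
person-time bookkeeping assigns non-progressors the full horizon and
progressors a configurable fraction (default one half, i.e. events
uniform over follow-up); real studies' individual follow-up times are
generally not recoverable from published summaries, so rate point
estimates depend on this convention while count-based quantities do
not.

The prediction model is binary logistic regression (maximum likelihood
via Newton/IRLS, coefficient tolerance 1e-8, 100 iterations) of the
5-year outcome on age, sex, family history of diabetes, BMI, HbA1c and
TAR, with the TAR odds ratio expressed per percentage point — the only
scale on which published per-unit effects of order 1.06 are plausible
given group TAR medians of a few percent. There is no censoring model:
the outcome horizon is fixed and lost-to-follow-up subjects are assumed
excluded upstream. Rank-deficient designs raise an error naming the
collinear columns; perfect or quasi-perfect separation (detected by
statsmodels' convergence failure or coefficients exceeding 50 in
absolute value) raises rather than returning garbage — with ~20 events
and six covariates this occurs for a noticeable minority of simulated
cohorts, which is a property of the design size, not a bug.

Discrimination is the apparent (in-sample) AUC in the rank
(Mann–Whitney) formulation with ties counted one half, with a DeLong
95% interval; apparent AUC matches single-cohort reporting practice. A
stratified K-fold cross-validated AUC is available
(`epi.cross_validated_auc`) but off by default. Calibration is the
Brier score. Wald intervals are used for odds ratios throughout.

## The synthetic cohort generator

The generator emulates a population-based CGM study: 499 non-diabetic
adults, 22 of whom develop T2D within 5 years. Group-conditional
calibration targets (means/SDs for age, BMI, FPG, HbA1c, HOMA-IR;
prevalences for sex, family history and ATP-III components; median/IQR
for TAR; wear-day probabilities pooled over the cohort) are taken from
the published group summary tables and are the package defaults.

**Marginals.** Continuous labs are truncated normals whose *underlying*
parameters are solved numerically so the *truncated* moments match the
targets. Bounds encode enrolment: FPG < 126 mg/dL (below the
diagnostic threshold; the solver attains the printed moments there) and
HbA1c < 7.4%. The HbA1c upper bound deliberately exceeds 6.5%: a
single elevated baseline value is not a diabetes diagnosis under the
two-sample rule, and the printed progressor-group SD of 0.7 around a
mean of 5.8 is *unattainable* by any normal truncated at 6.5 (that
combination is the exponential limit of the family), so the printed
dispersion itself implies unconfirmed elevated baselines were present.
HOMA-IR and triglycerides are lognormal (right-skewed, as SD ≈ mean
suggests); fasting insulin is back-computed from HOMA-IR and FPG so the
index is internally consistent. TAR propensity uses a two-piece
lognormal quantile model anchored on the printed median with separate
log-scale spreads below and above it, matching all three printed
quartiles exactly; a symmetric lognormal would overstate the
non-progressor upper tail (95th percentile ≈ 42% TAR instead of ≈ 21%).
Propensities are capped at 60%.

**Dependence.** A Gaussian copula links (HbA1c, FPG, TAR propensity,
BMI, HOMA-IR, metabolic load) with default latent correlations of 0.83
(TAR–HbA1c) and 0.76 (TAR–FPG) — the two published pairwise
correlations — and moderate values elsewhere. ATP-III component flags
are Bernoulli draws with the configured prevalences, coupled through
the latent metabolic-load factor (loading 0.55) so components
co-occur; the continuous measures behind each flag (waist,
triglycerides, HDL, blood pressure) are then drawn from the
flag-consistent truncated conditional, so reclassifying the generated
table recovers the configured prevalences exactly in expectation.
Hyperglycaemia (FPG ≥ 110) and the syndrome itself are emergent, not
directly set. Age is drawn independently; in reality age correlates
with the metabolic variables, which this generator does not model.

**Traces.** A subject's trace is basal + circadian + meals + noise:
basal is anchored to the HbA1c-implied estimated average glucose
(28.7·HbA1c − 46.7), with the between-meal level capped so that its
circadian *peak* stays at 130 mg/dL — non-diabetic regulation keeps
between-meal glucose below the high-TIR threshold, elevated averages
being expressed through excursions; capping the peak rather than the
basal alone matters, since otherwise high-HbA1c subjects carry a floor
on TAR from circadian peaks plus noise alone. The circadian component
is a sinusoid (subject-lognormal amplitude, median 8 mg/dL, trough
04:00);
three daily meals (08:00, 13:30, 20:30 with 30-min jitter) have
gamma-shaped excursions `x·e^(1−x)` with a 36-min rise constant; sensor
noise is AR(1) with stationary SD 6 mg/dL and lag-1 correlation 0.8.
The subject's meal amplitude is solved by bisection so that the
*realised* fraction of readings above 140 mg/dL (on the already-drawn
noise path, using the same rounded-value predicate as the range metric)
equals the subject's TAR propensity. Solving against the realised path
rather than its expectation is deliberate: the published TAR quartiles
are realised values, and calibrating in expectation leaves the group
median biased upward by the mixing of symmetric realisation noise with
a right-skewed propensity distribution (measured bias ≈ +0.5 TAR
points before the change). The cost is that within-subject TAR
realisation noise is essentially removed; repeat-wear variability in
real data is therefore not represented. TBR is emergent and close to
zero, consistent with published medians of 0, but the generator
under-represents the upper quartile of TBR (real cohorts show up to
~1.7% in the upper quartile; simulated non-progressors reach ~0.6%).

**Causal-logistic mode.** Covariates are drawn from the non-progressor
(general non-diabetic population) calibration and the outcome is
Bernoulli with `logit p = β₀ + Σ β·x + β_TAR·TAR%`, the intercept
solved by root-finding so expected prevalence hits a target (default
4.4%). Default non-TAR coefficients are plausible epidemiological
values (e.g. OR 1.03/year of age, 1.10/BMI unit, 3.0/HbA1c %); they
matter only through confounding strength, since recovery is judged
against the generating TAR coefficient.

**Determinism.** Cohorts are bit-reproducible given the config seed;
traces use per-subject child generators spawned from a trace seed, so
subsets reproduce independently. The pipeline fans one seed into
per-stage seeds by fixed offsets.

## What passing tests show — and what they cannot

Stochastic reproduction checks refit the full pipeline on cohorts from
this generator, so they validate the *analysis machinery* (metrics,
model, intervals) and the *calibration to published group summaries*.
They cannot certify behaviour on real CGM data, which has sensor drift,
missingness patterns, irregular meals and within-subject variability
that the generator does not model.

One published headline is structurally out of reach of this generator
family: an apparent AUC of 0.94 for the six-covariate model. Under any
elliptical-copula reconstruction of the published group marginals, the
strong reported TAR–HbA1c coupling makes the predictors redundant and
caps the mean apparent AUC near 0.86 (sensitivity analysis: removing
the TAR–HbA1c/FPG coupling entirely — contradicting the published
correlations — only reaches ≈ 0.89). Reproducing 0.94 would require
joint tail behaviour of the real 22 progressors that printed
means/SDs/quartiles and two pairwise correlations do not pin down. The
package reports what the calibrated generator actually yields rather
than re-weighting it toward the published value; the corresponding
check is expected to flag this gap.

A published distributional-test p-value (0.034) is likewise not a
reproduction target: the underlying test statistic and null scheme are
unknown, so the permutation test here is validated by its type-I error
behaviour instead.

## Problem sizes

Default analysis scales were chosen as desk-scale study conditions:
20 replicate cohorts of 499 for model-metric summaries, 2,000 traces
for TAR-distribution estimates, 10,000 subjects for parameter recovery,
200 Monte-Carlo replicates at 199 permutations for the type-I error
check. At these sizes the full test suite and the reproduction script
each run in about one to two minutes on a single CPU. Medians of
heavy-tailed TAR distributions remain noticeably variable even at
n = 2,000 (SE ≈ 0.25 TAR points), so reproduction checks on the median
carry a small seed-dependent failure probability by construction.
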