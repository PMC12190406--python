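# Methods

This note documents the models, conventions, defaults and numerical
choices of `cuemed`, module by module, and what the validation
experiments do and do not establish.

## Synthetic study generator (`cuemed.synthetic`)

The generator emulates a three-group cue-conditioning experiment: groups
Heat, Salt, Sugar; five runs of twelve trials per subject; ten
conditioning trials in which the High cue is always followed by the
subject's High stimulus level and the Low cue by the Low level; fifty test
trials in which each cue is followed by its conditioned level or a Medium
stimulus with probability 0.5.  Cue order is uniformly randomized subject
to High/Low balance; the schedule's marginal probabilities are the design
parameters, and no further counterbalancing constraints are imposed.

Ratings follow a linear mixed model on the shared codes (level Low/Medium/
High → −1/0/+1; cue High/Low → +0.5/−0.5, so effects are directly
comparable to High−Low contrasts):

```
intensity = β0[group] + βL·level + (βC + uC,i)·cue + βT·(trial − mean) + u0,i + ε
```

and analogously for valence, whose level slope is negative for the
aversive groups (Heat, Salt) and positive for Sugar.  The
`paper_defaults` parameter set plants the published fixed-effect
estimates — intensity level slope 1.940, intensity cue effect 0.301,
valence level slope ±1.662, valence cue effect −0.201, and a Heat−Salt
intensity intercept contrast of −1.146 — as generator truth.  Quantities
the source results do not report numerically are package defaults chosen
once as realistic for 0–10 visual-analogue ratings: trial drift
−0.005/trial, subject intercept SD 1.0, subject cue-slope SD 0.2,
residual SD 1.2.  Ratings are clipped (not resampled) at the scale bounds
and the clip count is logged; clipping attenuates recovered slopes by a
few hundredths of a rating unit, visible in the recovery experiment.
Missing trials are independent Bernoulli(0.05) per trial, capped at 13%
per subject; missing ratings are NaN and handled listwise downstream.

Brain data are generated directly as per-trial coefficient images — the
output a subject-level beta-series GLM would produce — on a small grid
(default 12³, 3 mm affine).  Within a designated mediator region, trial
activation is `m_t = a_i·x_t + η_t` with subject slopes `(a_i, b_i)` drawn
bivariate normal (configurable correlation), and the subject's rating is
incremented by `b_i·m_t`, so the region is a true mediator by
construction; all other voxels are i.i.d. nuisance noise.  The trial-level
region noise η is essential: without it the mediator is collinear with the
cue and path b is inestimable.  What the generator does *not* emulate:
spatial autocorrelation and physiological noise, scanner drifts, realistic
HRF variability, non-Gaussian rating distributions, structured
missingness.  Passing recovery tests therefore demonstrate correctness of
the estimators under the assumed model, not robustness to real fMRI
artifacts.

Motion quality control excludes subjects whose mean Euclidean-norm motion
derivative strictly exceeds 0.3 (a value exactly at the threshold is
retained), mirroring the study-level exclusion rule.

## Calibration (`cuemed.calibration`)

Per subject and modality, an OLS line relates stimulus magnitude to
rating; with replicate trials the fit uses the mean rating per magnitude
(raw-trial fitting is an option).  r² is the squared sample correlation
and is defined as 0 when the ratings have zero variance, a conservative
convention that makes such subjects ineligible rather than dividing 0/0.
Eligibility requires r² strictly above 0.4.  Level selection inverts the
line at targets 2/5/8; predicted magnitudes above a delivery maximum
(e.g. 1 M sucrose) are clamped and flagged.  The adaptive procedure is
exposed as repeated refits plus an inverse-prediction proposal rule for
the next probe; the full staircase schedule of the original protocol is
intentionally not reproduced.  Valence is computed as
unpleasantness − pleasantness with an explicit sign option, since the
bivalent convention differs between labs.

## Single-trial GLM (`cuemed.trial_glm`)

Two unit-peak HRFs are provided.  The contrast-agent-style response is the
three-exponential mixture `0.184/1.5·e^(−t/1.5) + 0.330/4.5·e^(−t/4.5) +
0.670/13.5·e^(−t/13.5)`, sign-flipped so activation is positive and scaled
to peak 1; the constants are fixed in source so tests are exactly
reproducible.  The canonical form is a difference of gamma densities
(shapes 6 and 16, undershoot ratio 1/6) peaking near 5 s.  Event boxcars
are built on a 0.1 s microtime grid, convolved, and decimated to scan
times; the microtime grid bounds discretization error of the convolution.
Trialwise designs give each outcome event its own regressor; nuisance
columns (motion, swallow/rating/rinse boxcars) are appended unchanged and
never analyzed.  Estimation is OLS with an explicit rank check that names
offending columns; generalized least squares with autoregressive noise is
deliberately out of scope.  VIFs are computed per run on mean-centered
columns, `VIF_j = 1/(1 − R²_j)` from regressing column j on all others
(constant columns are excluded and reported NaN; perfect collinearity is
flagged +inf), and trials with VIF strictly above 2 are dropped before
mediation.

## Behavioral mixed models (`cuemed.behavioral`)

Cue, stimulus level and trial are mean-centered within the analysis
subset; Group is dummy-coded with Salt as the reference (so the two
dummies are Heat-vs-Salt and Sugar-vs-Salt), Modality is Heat vs Tastes,
Aversiveness is Heat+Salt vs Sugar.  Follow-up models restrict to medium
trials, where the level code is constant and dropped.  Fitting uses
statsmodels `MixedLM` (ML by default, REML selectable) with a per-subject
random intercept and cue slope; singular random-effect fits are flagged
and refit with intercept only, and the simplification path is recorded in
the result rather than silently applied.  Fixed-effect p-values are Wald
tests under the normal approximation — `MixedLM` provides no
Satterthwaite degrees of freedom — and every result records
`pvalue_method` so downstream reports are explicit about it.  The default
optimizer chain is BFGS → Powell → CG; L-BFGS was observed to diverge on
these likelihoods.  Model comparison ranks by AIC and provides
likelihood-ratio tests for nested pairs fitted on identical data.

## Multilevel mediation (`cuemed.mediation`)

Subject-level paths come from closed-form centered OLS; the same code path
serves scalar and voxelwise inputs, so a single-voxel map reproduces the
scalar pipeline exactly.  The identities `c − c' = a·b` (per subject) and
`ab = mean(aᵢ)mean(bᵢ) + cov_n(aᵢ,bᵢ) = mean(aᵢbᵢ)` (population, 1/n
covariance denominator) hold algebraically and are asserted to 1e−10 and
1e−12 in the tests.  Design choices where the field's conventions are
open: the second level is unweighted (every subject counts equally; an
inverse-variance option exists but is off by default); X, M, Y enter in
raw units (standardization is an option, not the default); trials with
missing ratings or VIF exclusions are removed listwise per subject before
fitting.

Inference is a percentile bootstrap over subjects: n_boot multinomial
resamples (default 10,000; seeds mandatory), recomputing the population
statistics per draw, with two-tailed p = 2·min(P(draw ≤ 0), P(draw ≥ 0))
floored at 1/n_boot.  Degenerate resamples consisting of a single unique
subject are redrawn and counted.  **Known limitation:** the percentile
bootstrap of a mean-like statistic is anticonservative at small n — its
implied confidence intervals are slightly too narrow — so at n≈20
subjects the ab test's realized type-I error exceeds the nominal 0.05 by
roughly 0.02–0.04 regardless of implementation; the validation suite
measures this directly (`validation.bootstrap_type1_error`).
Bias-corrected variants do not repair this (for products of means they
are, if anything, more liberal); a studentized bootstrap would, but is not
part of the implemented method.  With ~30+ subjects the miscalibration
shrinks toward nominal.

Moderated mediation regresses each subject-level quantity (a, b, aᵢbᵢ, c,
c') on a level-2 design with intercept and documented dummies (Heat>Salt,
Salt>Sugar; Modality Heat=1; Aversiveness Sugar=1), with subject-resampled
bootstrap p-values; the intercept of a design containing a factor is the
path estimate controlling for that factor.

The voxelwise wrapper runs everything as array operations over masked
voxels; voxels where any subject's mediator is collinear with the cue
come back NaN rather than aborting the map.

## Signature expression (`cuemed.signatures`)

Expression is the dot product of a fixed weight map and an image over the
pattern support; grids must match exactly — no resampling, because
interpolation would silently change dot products.  When image and pattern
support disagree, the intersection is used, missing voxels contribute 0,
and the coverage fraction is reported.  Group tests are the one-sample t
against zero (zero-variance inputs are flagged degenerate, not infinite)
and a one-way ANOVA with pairwise t-tests Bonferroni-multiplied by the
number of pairs.  Path-level signature tests express each subject's
path-coefficient map and feed the scores to the same two tests — no new
statistics.  Published signature weight maps are licensed artifacts and
are not bundled; synthetic patterns stand in for them throughout.

## Map thresholding (`cuemed.thresholding`)

BH-FDR runs over masked voxels (statsmodels step-up; the tests verify it
against the direct definition) and returns the realized threshold.
Cluster rules are named presets: mediation maps use p < .001 with k ≥ 3
and growth at p < .005 then p < .01; exploratory univariate maps use
p < .001 with k ≥ 10 and no growth.  Growth iteratively annexes
above-threshold voxels adjacent to an existing cluster; it never creates
new clusters, is monotone, and resolves ties between adjacent clusters to
the lower cluster label (a deterministic, order-free rule).  Contiguity
defaults to 6-connectivity (faces), configurable to 18/26, since
"contiguous" does not pin down a neighborhood.  Small-volume correction
defaults to sign-flip max-statistic permutation on subject-level maps —
exact under exchangeability of subject signs and cheap at desk scale —
with an analytic Bonferroni fallback; random-field-theory FWE is out of
scope.  Conjunction is the voxelwise AND of individually thresholded
masks (minimum-statistic conjunction).

## Pipeline (`cuemed.pipeline`, `cuemed.cli`)

A single YAML config drives all stages; the schema fills defaults and
rejects unknown fields, and every stochastic stage must carry an explicit
seed — there are no hidden defaults outside the schema.  The manifest
records config, package versions, completed/failed stages, and SHA-256
hashes of every artifact; identical configs reproduce identical hashes.
Tabular outputs are TSV; images are NIfTI (per-subject 4D beta stacks,
3 mm isotropic affine, 0-based voxel indices alongside affine-mm peak
coordinates in cluster tables).  The CLI is a thin wrapper: each
subcommand toggles stages and calls `run_pipeline`.

## Validation experiments (`cuemed.validation`)

Problem sizes are chosen to keep each experiment at desk scale.

- **Behavioral recovery** — 30 subjects/dataset (10 per group), full 60-
  trial schedule, 20 seeds (10 in the acceptance script): refit the
  generating mixed models and compare mean recovered coefficients to the
  planted `paper_defaults`.  The valence model includes Level×Group
  interactions because the planted level slope flips sign between
  aversive and appetitive groups.  Tolerances (0.1 rating units for
  within-subject effects, 0.35 for the between-subject group contrast)
  cover Monte-Carlo error plus the documented clipping attenuation.
- **Mediation algebra** — 200 random OLS instances; identity residuals at
  1e−10/1e−12.
- **Bootstrap type-I** — 500 null datasets, 20 subjects × 40 trials,
  n_boot = 2000; measures the anticonservatism discussed above.
- **Planted-mediator recovery** — frozen strong-effect regime (12³ grid,
  27-voxel region, a = b = 0.9 with SD 0.2, unit noise, 15 subjects,
  n_boot = 2000, q = .05), 100 simulations; detection means more than
  half the region's voxels survive whole-map FDR.  The regime was chosen
  by power analysis of the planted effects before freezing.
- **Round trips** — calibration fit→invert→forward at 1e−9; noiseless GLM
  beta recovery at 1e−8.
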