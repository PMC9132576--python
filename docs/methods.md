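# Methods

`brainaccel` asks a single epidemiological question in several statistical
forms: do the neurocognitive changes seen in type 2 diabetes mellitus (T2DM)
look like ordinary brain aging, arriving early and progressing faster?  The
package implements the full analysis chain on tabular cohort data and
volumetric imaging, and ships a synthetic-data generator that plants known
values for every estimand so the chain can be validated end to end without
access-controlled biobank data.

## Cohort model and eligibility

A cohort is a table of subjects with demographics (age in integer years, sex,
college-degree education, measured blood pressure), disease variables (T2DM
status, up to three self-reported onset ages, medication flags, BMI), and
outcome measures.  Derived variables:

* **Hypertension** — systolic > 140 mmHg or diastolic > 90 mmHg, both strict.
  A missing measurement yields a missing flag, never `False`, because the
  flag is a matching key.
* **Onset age** — the mean of the available onset reports (1–3 visits);
  averaging across visits reduces recall error.
* **Duration** — age minus mean reported onset, clipped below at zero.

Eligibility is applied in a fixed order with first-failure attribution, so
exclusion counts always partition the input: (1) females who did not report
menopause or who report ongoing hormone therapy are removed (the menopausal
transition is a strong confound at the 50-year entry age); (2) diabetic
subjects with mean reported onset below 40 years are removed, a standard
guard against type 1 diabetes contamination.  Onset exactly 40 is eligible.
Diabetic subjects with no usable onset report cannot be checked against the
rule and are excluded, logged under the same rule.

## Matching

Cases and controls are paired 1:1 only within strata defined by the exact
keys (default: integer age, sex, education, hypertension) and, for the
medication contrast, by half-open bins `[origin + j·w, origin + (j+1)·w)` of
age (w = 5 y) and duration (w = 3 y).  Key-compatibility is an equivalence
relation, so the maximum 1:1 matching size is exactly
`Σ_strata min(#cases, #controls)`; the implementation pairs greedily in
sorted-id order, which attains that maximum and makes the output invariant
to input row order.  Tests verify the size against a brute-force maximum
bipartite matching (networkx) on small instances.  How surplus controls are
discarded is not statistically identified; sorted-id determinism is this
package's choice for reproducibility.  No caliper or propensity matching is
offered — exactness is the design.

## Effect estimation

Effects are ordinary least squares coefficients with an intercept: the model
is `outcome ~ 1 + factor (+ covariates)`, two-sided t test, t-based 95% CI.
After exact matching the default model contains the factor alone; the
metformin contrast adds BMI as a disease-severity proxy.  Percent effects
divide the coefficient and its CI bounds by the mean outcome of the matched
control arm, giving unit-free "percent of healthy performance/volume"
numbers.  Regional maps fit the 45 bilateral gray-matter regions one at a
time on head-size-normalized volumes (volume divided by a per-subject
scaling factor) and attach Bonferroni-adjusted p-values with m = 45.
Cognitive and structural families use Bonferroni; voxelwise activity uses
Benjamini–Hochberg FDR (step-up, via statsmodels).  A user-supplied mapping
table can first coarse-grain a finer parcellation (e.g. 139 unilateral
regions) into the 45 bilateral regions by summation; no canonical mapping is
bundled because parcellations differ between atlas versions.

## ALFF

The amplitude of low-frequency fluctuation summarizes resting-state activity
per voxel.  Pipeline: linear detrend; unpadded real FFT; per-bin amplitude
`√2·|X(f)|/N`; ALFF = mean over bins with 0.01 ≤ f ≤ 0.08 Hz, edges
inclusive (for an on-bin sinusoid of amplitude A the per-bin value is the RMS
A/√2).  The absolute constant is immaterial: each subject's map is divided
by its gray-matter-mask mean, so the in-mask mean is exactly 1 and all group
statistics are invariant to global scaling.  Spatial smoothing uses a
Gaussian kernel parameterized by FWHM (σ = FWHM/2√(2 ln 2)) and is applied
frame-wise before amplitude computation by default (`smooth_first=True`, the
conventional image-space order); smoothing the amplitude map instead is one
flag away and is what the synthetic calibration uses, since amplitude maps
of independent-noise simulations are only exchangeable pre-smoothing.

Group inference fits the per-voxel OLS factor model with a vectorized
closed-form solver (verified against statsmodels per voxel in the tests),
converts t to z by two-sided tail-probability matching with sign preserved
(comparable across differing residual df), adjusts two-sided p-values by
FDR across in-mask voxels, groups suprathreshold voxels by face
(6-neighbour) connectivity separately per sign, and discards clusters below
the extent threshold (default 12 voxels).  Because adjusted p-values are
fixed per map, cluster voxel sets are monotone in q.  Voxel maps are
coarse-grained to regions by masked means over a label volume, which is also
how externally produced z-maps can be brought to the regional grain.

## Overlap and acceleration

*Overlap* is the bivariate Pearson correlation between two effect maps over
their shared, non-missing region (or domain) names, with the two-sided p
from the t transform on n − 2 df.  The default correlates raw coefficients;
percent maps rescale each region by its control mean and are available via
the `field` argument.

*Acceleration* is the ratio of the duration slope to the age slope of
whole-brain gray-matter volume, fitted in one joint OLS model
(`volume ~ 1 + duration + age`) within the diabetic arm so the coefficient
covariance is estimated rather than assumed zero.  The 95% confidence set
comes from Fieller's theorem: the set of ρ with
`(b₂² − t*²v₂₂)ρ² − 2(b₁b₂ − t*²v₁₂)ρ + (b₁² − t*²v₁₁) ≤ 0`.  When the
denominator is significantly nonzero this is a bounded interval; otherwise
the set is the complement of an interval or the whole line, reported with
`bounded=False` rather than silently truncated.  The point estimate always
lies in the set.  A delta-method interval is provided for comparison and
agrees to <1% relative width once |b₂|/SE > 50.  The age slope here is the
within-diabetic-arm fit; correlating against the healthy-control age slope
instead is possible by fitting the two models separately (at the cost of
v₁₂ = 0), but the joint fit is the default because a proper covariance makes
the Fieller set exact under the model.

## Meta-analysis

Study summaries (group mean, SD, N per arm and cognitive domain) are
converted to Cohen's d with the pooled-SD convention and variance
`(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`; a Hedges small-sample correction is
optional and off by default.  Domains scored lower-is-better (reaction
times) carry a direction flag and are sign-flipped so negative d always
means worse case performance.  Per domain, studies are pooled with
random-effects weights `1/(vᵢ + τ²)`; τ² is estimated by REML (bounded 1-D
optimization of the restricted likelihood, snapped to 0 when the boundary
is optimal) or DerSimonian–Laird in closed form.  Cochran's Q uses
fixed-effect weights; I² = max(0, (Q − (k−1))/Q)·100.  CIs are normal-based.
Studies contributing several tests to one domain are averaged within study
first by default, so no study is double counted.  Single-study domains are
reported with missing pooled statistics and a warning, never silently
pooled.  Bonferroni runs across the pooled domains.  Funnel exports give
(d, SE) points plus the pseudo-95% boundary around the pooled estimate.

## Synthetic generator

The generator defines the validation conditions; its defaults are fixed and
are what the tests and the acceptance script run:

* **Cohort**: ages uniform on [50, 80] (integer), 50% female, 33% degree,
  35% hypertension (blood pressures drawn from truncated normals consistent
  with the flag), 85% of females menopausal, 8% on hormone therapy.  Disease
  duration is exponential (mean 8.5 y) truncated to [0, min(31, age − 40)],
  so onset truth never violates the 40-year rule; onset reports add
  integer-rounded Gaussian recall noise (SD 1 y, clipped to ≤ age; visits 2
  and 3 missing at 15%).  Zero reporting noise yields exact (unrounded)
  reports, so noiseless runs recover generative parameters exactly.
  Medication classes among cases: 49% metformin-only, 35% unmedicated,
  16% other.  A head-size factor ~N(1, 0.08²) multiplies measured volumes.
* **Volumes**: 45 named bilateral regions with literature-plausible baseline
  volumes and age slopes between −0.28 and −1.0 %/year (steepest: ventral
  striatum, Heschl's gyrus; shallowest: thalamus, caudate).  The case offset
  is `k·age_slopes + perturbation` with k = 6 years of age-equivalent loss;
  the perturbation is a seeded Gaussian draw made orthogonal to both the
  constant vector and the age-slope vector and scaled to m times the
  centered norm of `k·age_slopes`, which fixes the planted Pearson overlap
  at exactly `1/√(1+m²)`.  The duration slope is `α·age_slopes` per region
  with α = 0.26 by default.  Residual noise is Gaussian, SD 8% of baseline
  per region (heteroscedastic across regions).  Overlap validations run with
  α = 0, because a nonzero duration effect adds another age-slope-
  proportional component to the case contrast and shifts the estimand.
* **Cognition**: five domains, linear in age from intercept 100 at age 50,
  additive case offsets sized to plant percent deficits of roughly −13.1,
  −6.7, −3.7, −2 and −1 percent of the healthy mean at age 65, noise SD
  15–20, missingness 5–15% per domain (NaN, never zero).
* **fMRI**: per subject, every voxel carries a sum of in-band sinusoids
  (frequencies shared within subject, phases independent per voxel) plus
  white noise; cluster definitions scale the sinusoid amplitude per group.

What the generator does **not** emulate: age-by-disease confounding
(prevalence is independent of age, so unmatched contrasts are already
unbiased — matching is exercised, not load-bearing), nonlinear aging
trajectories, spatial noise correlation and physiological/motion artifacts
in fMRI, site effects, and selection into imaging.  Passing tests therefore
demonstrate the estimators' correctness under the stated model, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

* Matching bins are half-open with origin 0; age is matched as integer years.
* Rank-deficient regression designs raise with the collinear terms named;
  duration exactly collinear with age raises in the acceleration fit.
* Fieller with all variances zero degenerates to the point ratio; a zero
  denominator with zero variance is an error.
* BH-FDR at q = 1 with extent 1 degenerates to "every in-mask voxel
  clustered", accepted as the boundary case of the thresholds.
* τ² REML uses `xatol` 1e-10 on a bounded bracket and snaps to zero when
  the restricted likelihood at zero is not worse than the interior optimum.
* Empty regions in label aggregation produce NaN with a warning; empty masks
  and zero global means are errors.

## Validation scale

The shipped validation simulations use cohorts of 2,000–8,000 subjects,
200–500 replicates for coverage and estimand-recovery checks, 20×20×20×200
fMRI grids with 10 subjects per arm and 40 runs for null FDR-cluster
control, and 1,000 random draws for the Fieller oracle comparison — sizes
chosen so each recovery check has simulation error well below its stated
tolerance while the whole suite runs on a laptop-class single core in a few
minutes.

## Known limitations

* The 45-region roster and its baseline volumes/slopes are a plausible
  stand-in parcellation, not a licensed atlas; real analyses should supply
  their own region table and mapping.
* Voxelwise inference treats voxels independently (no random-field or
  permutation cluster correction); the extent threshold is descriptive.
* The meta-analysis module pools user-supplied summary tables; it does not
  extract, screen, or harmonize literature data.
* Fieller sets are exact under joint normality of the two coefficients; with
  heavy-tailed residuals the coverage statement is asymptotic.
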