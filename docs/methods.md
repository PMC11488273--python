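# Methods

This package re-implements, as a tested pipeline, the outcome analysis of a
large naturalistic cohort of adolescents treated for eating disorders in
higher levels of care (inpatient, residential, partial hospitalization,
intensive outpatient): psychometric scoring, Jacobson–Truax reliable and
clinically significant change, percent of expected body weight, and
longitudinal mixed-effects models with predictor interactions. Because no
participant-level data are deposited, the pipeline runs on a synthetic
cohort generator that reproduces the study's data structure; everything
below is therefore about models and calibration, not about real patients.

## Instruments and scoring

Three self-report scales are scored from item-level responses:

* **EDE-Q global** — 22 attitudinal items on a 0–6 scale, partitioned into
  four subscales (restraint, eating concern, shape concern, weight
  concern); each subscale is the mean of its present items (at least half
  must be present), and the global score is the mean of the four subscale
  means. The published instrument shares one item between the shape- and
  weight-concern subscales; because the scorer requires a partition, the
  shared item is assigned to weight concern. The subscale map is
  configuration data on `ScaleSpec`, so alternative maps (including the
  exact published one, with the item duplicated into a 23-slot map) are a
  config change, not a code change.
* **PHQ-9** (9 items, 0–3, summed, 0–27) and **GAD-7** (7 items, 0–3,
  summed, 0–21). By default missing items are not prorated; proration
  (mean of present items scaled to the item count, rounded) is available
  via `proration_max_missing`.

Internal consistency is Cronbach's alpha on listwise-complete rows with the
population (1/n) variance convention; the same convention is used by the
brute-force covariance-matrix oracle in the tests.

## Reliable and clinically significant change

For each scale the reliable change index threshold is

    threshold = z * sqrt(2) * SD_admission * sqrt(1 - alpha),  z = 1.96.

With the study's admission SDs (1.59 / 7.08 / 5.74) and the
admission-timepoint reliabilities (0.96 / 0.89 / 0.90) this reproduces the
published thresholds 0.88 (EDE-Q), 6.51 (PHQ-9) and 5.03 (GAD-7).
Thresholds are carried at full precision internally; reports round to two
decimals but classification always compares at full precision, and all
comparisons are strict (a change of exactly the threshold is not reliable
change).

Clinical significance uses criterion "c",
`c = (sd_norm*m_clin + sd_clin*m_norm) / (sd_norm + sd_clin)`. The
adolescent community norms behind the study's cutoffs are published in
cited normative studies rather than in the analysis itself, so the cutoffs
ship as configured constants (2.71 / 9.48 / 7.97) and `criterion_c_cutoff`
is available whenever norms are supplied.

Each complete admission/follow-up pair falls into exactly one of five
groups: **normative** (below the cutoff at both timepoints),
**deteriorated** (reliable worsening), **unchanged** (clinical at admission,
no reliable change), **improved** (reliable improvement, still clinical),
**clinically significant** (reliable improvement crossing the cutoff).
Pairs that start in the normative range and end above the cutoff are not
covered by the published footnotes; we classify them as deteriorated when
the worsening exceeds the RCI and normative otherwise. Pairs with either
score missing are excluded from the reporting denominator.

## Percent of expected body weight

Expected weight comes from an LMS growth reference (Box–Cox power L, median
M, coefficient of variation S; value at deviate z is `M(1+LSz)^(1/L)`, with
the lognormal limit used for |L| < 1e-8). The default method is median
BMI-for-age × height², with median weight-for-age as an explicit fallback
when height is unavailable; the method used is recorded per result. L, M
and S are linearly interpolated on the age grid (months); ages outside the
grid raise rather than extrapolate, and such participants are excluded from
weight models with a logged reason. %EBW = 100 × observed / expected.

The repository ships a **synthetic** LMS reference — smooth logistic median
curves with magnitudes typical of adolescent growth references — so that
nothing needs downloading; it is explicitly not a national growth standard.
Real LMS CSVs (columns `measure, sex, age_months, L, M, S`) load through
the same `GrowthReferenceTable` interface.

## Linear mixed models

Symptom and weight outcomes use the Gaussian random-intercept model

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e),

with time as days since admission, controlling for age at admission and
total length of stay ("length of stay" is ambiguous between total and
level-specific; total is used). Estimation is maximum likelihood, not REML,
consistent with the full-information ML framing of the original analysis;
the likelihood is profiled over the variance ratio lambda = s2_b/s2_e so a
fit reduces to a one-dimensional bounded optimization of the profiled
deviance (converged at 1e-10 relative), with per-participant blocks
inverted analytically. The boundary s2_b = 0 is evaluated explicitly and
taken when it is at least as good, and is flagged on the fit. All rows with
an observed outcome and complete covariates enter the likelihood
(available-case ML), which is unbiased when missingness depends only on
observed variables — "full-information ML" as mixed-model software
implements it; no joint imputation model is fitted. Random slopes are out
of scope: the reporting granularity being reproduced is random-intercept.

Inference is Wald (z against the standard normal). Effect sizes are
semi-partial R² per fixed-effect term, `R2 = qF/(qF + nu)` with F the Wald
F and nu the containment-rule denominator dof: `n_obs - rank(X) -
(n_participants - 1)` for within-participant terms and `n_participants -
rank(between design)` for between terms, a term counting as within if any
of its columns varies inside a participant. Confidence intervals for R² are
parametric-bootstrap percentiles (default 200 replicates, seeded) rather
than an analytic beta approximation, because the published analysis's exact
dof variant is not identified.

## Negative-binomial mixed models

Binge-eating and self-induced vomiting episode counts use an NB2 model
(variance mu + mu²/theta, log link) with a Gaussian random intercept. The
per-participant marginal likelihood is approximated by the Laplace method:
a damped, vectorised Newton iteration finds the penalized mode of each
random effect (the penalized log-likelihood is strictly concave in each
b_i), and the outer L-BFGS-B optimizes (beta, log s2_b, log theta) with
internally unit-scaled design columns (gradient tolerance 1e-6). Wald
standard errors come from a central-difference Hessian at the optimum.
The linear predictor is clipped at ±30 so exploratory optimizer steps
cannot overflow. Tests hold the Laplace log-likelihood to within 0.5% of a
31-node adaptive Gauss–Hermite quadrature oracle and require the s2_b → 0,
theta → ∞ limit to match a plain Poisson GLM.

Participants reporting more than 500 episodes at any assessment are treated
as implausible self-reports: they are flagged and removed from count models
while remaining in all other analyses, with every exclusion logged.

## Contrast coding and multiplicity

Eating-disorder diagnosis (AN reference; BN, BED, OSFED/UFED) enters
predictor models with simple coding — level j's column is (k−1)/k for
level j and −1/k otherwise — so coefficients are level-vs-reference
differences while the intercept is the unweighted grand mean of level
means. In count models the reference is AN-BP among the binge-spectrum
diagnoses. Post-hoc models add 0/1 census-region dummies (South reference)
and level-of-care indicators. Family-wise error across the 17-model battery
uses Bonferroni: 0.05/17, reported as 0.003 and applied at full precision.

## Synthetic cohort generator

The generator is the study-conditions definition, not a tuning knob. Its
defaults are the published sample structure: n = 1,971; diagnosis mixture
AN-R .464, AN-BP .141, BN .057, BED .019, OSFED/UFED .319; comorbidity
prevalence .797; admitting level-of-care mixture IP .153 / RES .435 /
PHP .351 / IOP .061; age ~ truncated normal 14.84 (1.64) on 9–18 years;
total length of stay 79.97 (49.56) days truncated to [2, 386]; stepdown day
drawn from the admitting level's published stay distribution and clamped
inside the total stay; gender/race/discharge-reason mixtures as published
(diagnostic covariates for missingness realism only). Region marginals are
not published; a fixed plausible mixture (South .35, West .25, Midwest .25,
Northeast .15) was chosen once.

Outcome trajectories are latent Gaussian random-intercept processes whose
admission means and total variances match the published descriptives
(e.g. EDE-Q 3.62, variance 1.59² split 60/40 between person and residual)
and whose time slopes and predictor×time modifiers echo the published
fixed-effect magnitudes (EDE-Q −0.015/day; PHQ-9 −0.05; GAD-7 −0.03;
interaction shifts of −0.01 to −0.02/day) — a calibration so that sanity
bands on fitted models are meaningful, not a claim about ground truth.
%EBW for AN participants starts at 87.46 (10.48) with a mean
admission-to-discharge gain of 16.43 (SD 10.87) spread over the stay;
weights are only generated at admission and discharge, mirroring when the
study weighed participants. Counts are NB2 (gamma-mixed Poisson) for the
binge-spectrum diagnoses. Two participants receive implausible (>500)
episode counts and 4.3% receive a second treatment episode, so the
preprocessing rules are exercised end to end.

The measurement layer is switchable. With `include_items=True` (default)
item responses are generated under a parallel-items model and scores are
obtained by actually scoring the items, inheriting rounding and range
clipping; the continuous noise variance is set by inverting the
Spearman–Brown relation for the target alpha and subtracting 1/12 for the
variance added by rounding to the response grid. This hits the published
reliabilities (0.96/0.89/0.90) within ±0.02 at n = 2000, but clipping
attenuates the observed score SDs somewhat relative to the latent inputs
(e.g. EDE-Q admission SD ≈ 1.33 against a latent 1.59) — a known,
documented consequence of bounded discrete items. With
`include_items=False` the latent trajectories are recorded directly; this
model-faithful mode is what parameter-recovery simulations use, since there
the fitted model must be exactly the generating model.

Missingness is a logistic missing-at-random model on observed baseline
covariates (cisgender female, AN-R, comorbidity, routine discharge,
admission %EBW z-score — signs follow the published completer profile),
with the intercept calibrated by bisection so the marginal rates hit the
published 23.3% (stepdown, among the ~65.5% who step down) and 55.6%
(discharge). Admission assessments are never missing and staff-measured
weights are retained. The admission-severity×time interaction defaults to
zero in the generator: defining truth on an endogenous observed covariate
would make exact recovery ill-posed; it remains available through config.

What passing tests do and do not show: recovery and calibration on this
generator demonstrate that the estimation machinery is correct under the
stated models at the study's sample sizes and missingness rates. They do
not validate the substantive published coefficients, which require the real
data; the real-data tables are reproduced in *form* only.

## Numerical choices and problem sizes

* LMM profiled deviance: bounded scalar optimization on log-lambda in
  [−14, 14], xatol 1e-10; boundary lambda = 0 compared explicitly.
* NB-GLMM: inner Newton to a 1e-10 Newton decrement with per-group step
  halving (acceptance tolerance relative, because gammaln at large theta
  has an absolute noise floor); outer L-BFGS-B, gtol 1e-6.
* Bootstrap and every simulation path require a seed; identical seeds give
  byte-identical outputs, including written CSVs.
* Test-suite simulation sizes: oracle equivalence on ~20 small datasets
  (6–15 participants); parameter recovery on 100 replicates of 500
  participants × 3 assessments per family; calibration checks at n = 2000.
  The full pipeline run in `analysis/` uses the study-scale n = 1,971 with
  200 bootstrap replicates per R² interval.

## Known limitations

* The item generator's parallel-items model (equal loadings, equal errors)
  is stylised; real EDE-Q items are multidimensional by design.
* Clipping/rounding attenuates generated admission SDs below their latent
  targets (documented above); alpha calibration absorbs rounding but not
  range clipping.
* Count models on small subsamples (tens of participants with wide
  predictor designs) can be practically unidentified; the pipeline records
  such fits as failed rather than forcing convergence.
* The synthetic growth reference is a stand-in with realistic magnitudes,
  not a national standard; %EBW levels are therefore internally consistent
  but not externally comparable.
* No random slopes, GEEs, Kenward–Roger dof, or multiple imputation; the
  Gulliksen–Lord–Novick RCI variant is a registry hook only.
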