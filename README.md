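# edhloc

Outcome analysis for adolescents with eating disorders treated in higher
levels of care (inpatient, residential, partial hospitalization, intensive
outpatient). The package is aimed at treatment-outcome researchers who want
the full analytic chain of a large naturalistic cohort study as tested,
reusable code:

* item-level scoring of the EDE-Q (global = mean of four attitudinal
  subscale means), PHQ-9 and GAD-7, with Cronbach's alpha;
* Jacobson–Truax reliable change, `RCI threshold = z·√2·SD·√(1−α)`, and
  clinical-significance criterion "c" cutoffs, feeding a five-group
  classification (normative / deteriorated / unchanged / improved /
  clinically significant) and cohort change tables;
* percent of expected body weight, %EBW = 100·observed/expected, from LMS
  growth references (median BMI-for-age × height², or weight-for-age);
* random-intercept linear mixed models by profiled maximum likelihood
  (y_ij = x_ij'β + b_i + ε_ij), available-case under MAR, with Wald tests,
  semi-partial R² effect sizes and bootstrap CIs;
* negative-binomial mixed models (NB2, Laplace approximation) for
  binge-eating and vomiting episode counts;
* a seeded synthetic cohort generator reproducing the study's structure
  (diagnosis/level-of-care mixtures, three assessment points on a
  days-since-admission clock, item-level reliability targets,
  covariate-dependent MAR missingness at 23.3%/55.6%), so every stage is
  testable without any data download.

## Worked example

Simulate a study-scale cohort and run the full analysis:

```bash
python analysis/01_simulate.py --seed 1            # cohort + truth record
python analysis/02_descriptives_reliability.py     # descriptives, alphas
python analysis/03_reliable_change.py              # thresholds + change tables
python analysis/04_outcome_models.py               # symptom/weight/count models
python analysis/05_predictor_models.py             # predictor interactions
python analysis/06_missingness.py                  # MAR diagnostics
```

or equivalently, as one pipeline: `edhloc analyze --seed 1 --out results/pipeline`.

`03_reliable_change.py` prints the reliable-change thresholds computed from
each scale's admission SD and reliability,

```
reliable-change thresholds (z = 1.96):
  edeq   RCI  0.88   cutoff  2.71
  phq9   RCI  6.51   cutoff  9.48
  gad7   RCI  5.03   cutoff  7.97
```

meaning, e.g., an EDE-Q global change greater than 0.88 points exceeds what
measurement error alone would produce at 95% confidence, and a score
crossing 2.71 moves into the normative range. On the seed-1 synthetic
cohort the IP/RES change table begins

```
scale           interval  clinically_significant  improved  unchanged  deteriorated  normative  n_reporting
 edeq admit_to_discharge                    29.1      13.7       25.8           8.9       22.4          539
```

i.e. 29.1% of the 539 IP/RES-admitted adolescents with both assessments
reported a reliable EDE-Q improvement that crossed into the normative
range. `02_descriptives_reliability.py` reports the generator hitting its
reliability calibration (EDE-Q α = 0.957, PHQ-9 0.880, GAD-7 0.891 at
admission), and `04_outcome_models.py` shows symptoms declining over
treatment in both admitting groups (e.g. EDE-Q slope −0.0099 points/day in
IP/RES, %EBW gain +0.20 %/day among AN), with significance flagged at the
Bonferroni-corrected threshold 0.05/17 ≈ 0.003.

All tables land under `results/` as plain CSV/markdown, with a
`manifest.json` recording seed, configuration hash and package version.

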