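# Methods

## The risk model

The package implements the COMPERA 2.0 risk score for pulmonary
hypertension, applied longitudinally to CTEPH patients treated with staged
balloon pulmonary angioplasty (BPA). Three noninvasive variables — WHO
functional class (WHO-FC), 6-minute walk distance (6MWD, m) and NT-proBNP
(ng/L; BNP as fallback) — each receive an integer point from a cutoff
table, and the score is their mean:

    score = (points_FC + points_6MWD + points_peptide) / 3

rounded half-up to one decimal. The 4-stratum tables grade 1–4 points per
variable, the 3-stratum tables 1–3. With three integer-point variables the
attainable 4-stratum means are {1.0, 1.3, 1.7, 2.0, 2.3, 2.7, 3.0, 3.3,
3.7, 4.0}; no x.x5 rounding tie can arise. Half-up rounding (not banker's)
is fixed for the optional two-variable fallback mode, where ties are
possible.

### Cutoff boundaries

The published point tables print integer ranges ("320–440", "> 440"), which
leaves the continuous boundary convention open. All bins here are half-open
and **closed on the worse side**: a value exactly at a cutoff takes the
higher-point bin (6MWD of exactly 440 m scores 2, NT-proBNP of exactly
300 ng/L scores 2). The shipped config makes every boundary explicit and
`validate_cutoff_table` rejects any override whose bins leave a gap,
overlap, or break monotonicity in the worsening direction. Patients missing
any scored variable are rejected (`MissingVariable`), mirroring the
exclusion rule of the registry cohorts the score was developed on; a
config flag enables mean-over-available scoring with ≥ 2 variables.

## Stratification policies

Six policies map the mean score to an ordinal stratum: three versions
(original, modified, hybrid) × two granularities (3-S, 4-S). The versions
differ only in decimal handling — nearest-integer rounding (original),
ceiling (modified), and a fusion that rounds to nearest below a switch
point (score < 2 in 3-S, < 3 in 4-S) and takes the ceiling at or above it
(hybrid). Each policy is carried as an explicit closed-interval table over
the one-decimal grid, which is the authoritative representation; the
rounding prose exists in the test suite and the acceptance script only as
an independent oracle, cross-checked exhaustively against the tables on
every attainable three-variable point combination. Intervals are validated
to partition the grid with labels monotone in the score. Two structural
properties hold by construction and are asserted in tests: labels are
nondecreasing in the score within each policy, and at every grid score
rank(original) ≤ rank(hybrid) ≤ rank(modified).

## Longitudinal analyses

Risk is assessed within 7 days before (`pre`) and after (`post`) each BPA
session. Time is measured in months from the first BPA session
(30.4375 days/month); administrative censoring falls at the configured
study-end date.

* **Composite clinical worsening** — earliest of all-cause death, unplanned
  PH-related hospitalization, unsatisfactory long-term response (NT-proBNP
  doubled or ≥ 1800 ng/L from baseline), or new/worsening right-heart
  failure; censored at study end otherwise.
* **Transition matrices** — stratum flows between two timepoints under one
  policy, complete-case per timepoint (patients lacking either assessment
  drop out of that matrix only, so per-analysis denominators can differ).
  "Improved" is any decrease in stratum rank; multi-step improvements are
  tabulated separately. Sankey-ready edge lists are emitted.
* **Stratum elimination** — the first session whose pre-procedural
  evaluation contains no patient of a given stratum. Because the source
  data do not fix how non-reassessed patients enter later denominators,
  both an *evaluated-only* and a *carry-last-stratum* variant are reported.
* **Sessions to endpoint** — for the low-risk endpoint, a post-session-k
  assessment counts k sessions and a pre-session-k assessment k−1; only
  patients above low risk at baseline are eligible. For the hemodynamic
  endpoint (mPAP below a configurable threshold, default 30 mmHg), only
  pre-session right-heart-catheter reassessments (sessions ≥ 2) count,
  since immediately post-dilation pressures are not a stable response
  measure; only patients with baseline mPAP at or above the threshold are
  eligible. Non-attainers are reported separately from the median (IQR)
  session counts.

## Censored-data statistics

`km_estimate`, `logrank_test`, `harrell_c` and `spearman_corr` are
first-principles implementations because they carry the headline model
comparisons; each is pinned to an independent oracle in the tests
(empirical survival and a hand-computed product limit; hand-computed O−E
sums and a permutation-uniformity check; O(n²) pair enumeration; the
midrank definition).

Conventions: subjects censored exactly at an event time remain in the risk
set for that time. For Harrell's C, a pair is usable if the earlier time
carries an event (or times are equal with exactly one event); tied
predictors on a usable pair and both-event time ties count 0.5, so
`c = (concordant + 0.5·ties) / usable` holds exactly, and negating the
predictor maps c to 1−c. The source analyses do not state whether their
C-index used stratum ranks or the continuous score, so the pipeline
computes and reports both. Cox fits use the Breslow tie approximation by
default (Efron via config) and logistic fits plain maximum likelihood, both
delegated to statsmodels behind the package's contracts: the lowest
observed stratum is the reference, levels with zero events (or separated
outcomes) are flagged inestimable rather than fitted, and every fit guards
the events-per-coefficient ratio ≥ 5:1 (warning by default, error by
config). P-values are two-sided at α = 0.05.

## Synthetic cohort generator

No patient-level data are distributable, so the generator emulates the
cohort structure the analyses assume; all defaults are the study
conditions, not tuning knobs.

* **Baseline mixture** over original-4S strata: 0.21 / 0.30 / 0.42 / 0.07.
* **Covariates per stratum**: WHO-FC categorical weights and 6MWD/mPAP
  normal parameters taken from the per-stratum baseline table of the source
  cohort (e.g. low-risk 6MWD 451.7 ± 74.6 m, overall mPAP ≈ 49 ± 12 mmHg);
  NT-proBNP log-normal with μ = ln(median) and σ solved from the printed
  IQR (σ = ln(q3/q1)/(2·z₀.₇₅)) — strictly positive and right-skewed, as
  the median (IQR) reporting implies.
* **Stratum-first sampling**: a point combination consistent with the
  target stratum is chosen with probability proportional to its mass under
  the stratum's covariate distributions, then each covariate is drawn from
  its distribution truncated to the chosen bin (inverse-CDF). Every
  generated assessment therefore scores into its stratum by construction
  — the property the parameter-recovery tests rely on. Draws keep a 0.06
  margin inside each bin so one-decimal output rounding cannot cross a
  cutoff. A covariate model with no mass in any point combination of its
  stratum raises `ConfigError`.
* **Dynamics**: each session improves the stratum by one rank with
  probability 0.6 (a second rank with conditional probability 0.1) and
  worsens it with probability 0.03. Session counts are drawn on {1..8}
  with median 3 (IQR 2–4); inter-session gaps are log-normal with median
  3 months (IQR 1.25–5). The mPAP trajectory falls ≈ 4 mmHg per session
  with sd 3 and a 15 mmHg floor — a generator convention, since no
  per-session hemodynamic magnitudes are published.
* **Events**: piecewise-exponential on the time-varying post-session
  stratum with monthly hazards (0.002, 0.006, 0.018, 0.054) — strictly
  ordered, adjacent ratio 3.0, consistent with the strongly monotone crude
  hazard ratios of the source cohort. Event types mix as 2:7:6:11
  (death : hospitalization : unsatisfactory response : RHF worsening).
  Death truncates later sessions; the trajectory is simulated before the
  event draw, an accepted simplification. First-session dates are uniform
  over the 2018-05 – 2021-10 enrollment window with censoring at
  2021-12-25.
* **Reproducibility**: one global seed, per-patient substreams via
  `SeedSequence(seed, spawn_key=(i,))`, so generating fewer patients leaves
  the others' draws untouched.

`recover_parameters` closes the loop: empirical baseline mixture, pooled
per-session improvement probability among improvable patients, per-stratum
exponential rates from person-time at the time-varying stratum, and a
pooled adjacent-stratum hazard ratio from a rank-linear Poisson fit.
Zero-event strata are flagged inestimable.

### What passing tests do and do not show

The generator reproduces marginal covariate distributions per stratum,
ordered hazards, improvement dynamics and administrative censoring. It does
**not** model within-patient covariate autocorrelation beyond the stratum
process, lesion-level BPA physiology, complications, measurement error in
WHO-FC grading, or informative censoring. Tests passing on this cohort
demonstrate the pipeline's correctness and the qualitative 4-S > 3-S
discrimination mechanism (hazard heterogeneity hidden inside the 3-S
intermediate group); they do not validate the clinical effect sizes.

## Problem sizes and numerical choices

Simulation-backed checks use 2000 patients for mixture recovery and the
directional discrimination property (20 independent cohorts), 1000 for
hazard-ratio recovery, and 250 for shared pipeline tests; these sizes put
Monte-Carlo error well inside the asserted tolerances (±2 percentage
points on the mixture, ±25% on the adjacent hazard ratio). Percentages are
rounded half-up to one decimal via exact decimal arithmetic, never binary
floats. The k-group log-rank statistic uses the generalized inverse of the
(k−1)-dimensional covariance block when singular. Truncated-normal draws
clip the uniform variate to [1e−12, 1−1e−12] before inversion.

## Known limitations

* Cox/logistic adjustment sets are generic; the source study's specific
  multivariable confounder sets are out of scope.
* The generator's mPAP trajectory and session-truncation-after-death are
  conventions, not estimates.
* The printed integer cutoff ranges cannot distinguish boundary
  conventions; a cohort scored with a different boundary rule could differ
  for measurements lying exactly on a cutoff.
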