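# Methods

## The model family

`hosprisk` implements a family of logistic regressions for the
probability that a hospitalized patient dies between admission and seven
days after discharge (the 7-day window counters discharge bias — deaths
shortly after discharge that in-hospital mortality misses). The
covariates come in three blocks:

* **background risk** — age in years (linear) and gender (M = 1);
* **time-exposure risk** — time spent hospitalized treated as a
  cumulative dose of risk that varies with the time of week;
* **disease risk** — the Charlson comorbidity index as a raw integer
  score.

The exposure block exists in three resolutions. Variant *a* is the raw
length of stay in days. Variant *b* splits it into weekday and weekend
days plus the admission hour. Variant *c* — the heart of the package —
cuts every week into 21 blocks (night 00:00–08:00, daytime 08:00–17:00,
evening 17:00–24:00, per day of week) and counts, for each block label,
how many calendar block-instances the stay intersects:

    logit P(death) = β₀ + β₁·age + β₂·gender + β₃·Charlson
                   + β₄·admission_hour + Σ_b β_b·count_b

Three within-day samples exceed the Nyquist rate (2/day) for a signal
with one cycle per day, so the grid can represent the diurnal mortality
rhythm without aliasing; a weekday/weekend split with a linear
admission-hour term cannot.

Named presets assemble the published family: model1 (background),
model2a/b/c (exposure only), model3 (disease), model4a/b/c
(background + exposure), model5a/b/c (full), and refits of the full
model within one DRG (`model6:<drg>`) or one admission route
(`model7:ED`, `model7:non-ED`). The intercept is always estimated and
never counted in a model's "number of variables" (2, 1/3/22, 1, 3/5/24,
4/6/25).

## Exposure-encoding semantics

* Stays are closed intervals `[admission, discharge]` of naive local
  clock time; block boundaries are half-open, so 17:00 is the first
  instant of evening. No DST handling: its effects are far below the
  8–9-hour block resolution.
* Any non-empty intersection with a block-instance counts as one full
  dose; a stay meeting the same weekly label in two calendar weeks
  counts it twice. A zero-length stay counts its single containing
  block, so every admission has exposure ≥ 1.
* The batch encoder exploits the fact that block-instances form a
  global integer sequence whose labels repeat with period 21, reducing
  counting to two floor divisions per (stay, label); a minute-scan
  oracle in the test suite checks exact agreement.
* Admission time is a single continuous hour-of-day in [0, 24),
  matching a one-variable budget for "admission time".

## Charlson comorbidity index

The standard ICD-10 prefix mapping ships as a 17-group TSV fixture
(weights 1×10, 2×4, 3, 6×2). Codes are normalized (uppercased, dots
stripped) and matched by prefix; each group counts at most once; within
the two hierarchical pairs (diabetes with/without chronic complication,
metastatic vs other malignancy) only the more severe member scores.
Unknown codes are ignored at debug-log level. Severity categories: 0
zero, 1–2 mild, 3–4 moderate, ≥5 severe. Age adjustment is not applied
(age is its own covariate). Users may supply a replacement table with
the same layout.

## Fitting and evaluation

Maximum likelihood via Newton iterations (statsmodels `Logit` behind
`fit_logistic`), convergence tolerance 1e-10, gradient max-norm
reported. Rank-deficient designs and (quasi-)perfect separation raise
errors rather than being silently penalized — a ridge fallback would
corrupt AIC/BIC comparisons across the family. Predictions clamp the
linear predictor to ±35 so probabilities stay in the open unit interval.

Evaluation is prospective: training on admissions before the test year,
testing on the test year (records after it are dropped with a log
line). AUC is the Mann–Whitney concordance with ties at ½; its CI uses
DeLong's placement-value variance (hand-implemented; no installed
package exposes it), with a stratified bootstrap option. AIC = 2k − 2L
and BIC = k·ln n − 2L come from the training fit — they are
training-likelihood quantities by definition. The operating point
maximizes sensitivity + specificity over the distinct predicted scores
(predicted-positive means score ≥ cutoff; ties break toward the higher,
more specific threshold); sensitivity, specificity, PPV, NPV and
accuracy are reported there in percent, with PPV/NPV as NaN when no
record is predicted in the corresponding class. The cutoff is also
reported as the odds p/(1−p). Performance by length of stay buckets
records by ceil(LOS) (same-day stays in bucket 1, a pooled tail at
`max_day`, default 28); one-class buckets report NaN.

## Forecasting

A risk trajectory profiles the fitted full model over hypothetical
discharges 1…horizon days after admission, at whole-day increments.
Each point is the model's prediction for the literal record with that
discharge (bit-identical by construction), so shifting the admission by
exactly seven days leaves the trajectory unchanged. The curve does not
condition on survival to the current day — it is the static model's
view of cumulative exposure cost, not a discrete-time survival update.

## The synthetic cohort generator

The administrative collection the method was built for is not public,
so the generator emulates its statistical shape and carries its own
ground truth for recovery testing. Defaults (the study conditions):

* eight age bands with shares 10.2/4.4/21.9/25.2/13.5/12.8/9.9/2.2%
  (renormalized — the printed values sum to 100.1%), uniform age within
  band; gender 54.7% F / 45.3% M;
* Charlson categories 68.6/20.0/6.8/4.5% (renormalized), realized as
  ICD-10 code lists whose fixture score equals the drawn target;
* LOS log-normal with median 1 day and mean 3 (σ = √(2·ln 3) ≈ 1.48),
  truncated at 180 days;
* admission instants uniform over the 21 weekly blocks and over full
  weeks of 2005–2007 (nothing is published about admission-time
  marginals; a non-uniform profile is configurable);
* 11.8% of deaths dated 1–7 days post-discharge (23,819 of 201,647),
  the rest in-hospital;
* DRG labels: five condition groups known for day-to-day risk variation
  (R61, E02, F70, E64, J62) at 1% each plus a 95% pooled rest; ED route
  probability 0.4.

**logit-exact mode** draws the death indicator from exactly the full
model's linear predictor. True coefficients are anchored to the
demographic gradients the generator emulates: age +0.055/yr (the logit
of band death rates rises from ~0.2% at age ≤5 to ~19.6% at 85+), male
+0.34, Charlson +0.40/point, admission hour +0.01. The period profile
encodes the weekly risk shape the analysis targets: weekday daytime is
the reference at a slightly negative baseline (−0.15; daytime care does
not add risk), weekday nights/evenings +0.10/+0.20 relative, weekend
nights/evenings +0.40/+0.48, and weekend daytime exactly ln(1.7) above
weekday daytime so the Sunday-vs-Monday daytime per-dose odds ratio is
1.7. The slightly negative baseline keeps the net dose a modest +0.17
logit per day of stay; an all-positive profile makes cumulative risk
explode over the log-normal LOS tail, concentrating nearly all deaths
in saturated long stays and destroying identifiability of the per-block
contrasts. The intercept (−9.932) was calibrated once, by solving for
the marginal death rate 1.5% on a large probe cohort, and frozen.

**block-hazard mode** is the deliberate-misspecification testbed: risk
accrues as a hazard rather than through the logistic form. Each
occupied block contributes λ_b = λ₀·(1 + A·cos(2π(m_b − peak)/24))
(block midpoint m_b, amplitude A = 0.8, peak 21:00) times a weekend
multiplier (1.7), and the block of admission additionally contributes
`admission_acuity_weight` (30) doses of its λ_b — the admission-indexed
component of the weekly mortality pattern (sicker patients present out
of hours). P(death) = 1 − exp(−H), with H further scaled by
exp(0.01·(age − 45)). The 21:00 peak puts the trough mid-morning and
leaves both evenings *and* nights elevated — a non-monotone within-day
shape. This matters: with an evening peak at 19:00 the three block
hazards are monotone in clock time, and a linear admission-hour term
(model 2b) captures most of the cycle; likewise, without the
admission-acuity term deaths concentrate in long stays, where the
fine-grained and coarse exposure models rank patients identically. In
either of those designs the fine-grid model's sampling advantage is
invisible at cohorts of ~10⁵ admissions, and the expected ordering
AUC(2c) > AUC(2b) reverses under estimation noise.

What the generator does **not** emulate: seasonal and secular trends,
hospital identity and clustering, transfers and readmissions,
admission-rate variation across the week, realistic principal-diagnosis
coding, and the correlation between LOS and diagnosis. Passing tests
therefore demonstrate the machinery and its statistical behaviour under
the stated structure, not performance on real administrative data —
the published AUCs on the source collection (11.7M admissions) are not
reproducible at desk scale.

## Validation and pipeline

CSV records failing any rule are excluded and attributed to the first
failing rule in the fixed order admission_date, discharge_date,
date_order, death_date, diagnosis, drg, age, gender (the rule list is
standard administrative cleaning; the precedence is this package's
choice). The pipeline driver (simulate/load → validate → split → fit →
evaluate → forecast) is deterministic given its seed and writes every
artifact as CSV/JSON.

## Problem sizes and numerical choices

The test and acceptance suites size their simulations for a desk-class
machine: parameter recovery on one 200,000-admission cohort; the
Nyquist ordering on ten 120,000-admission block-hazard cohorts; the
full-model-dominance suite on ten 50,000-admission cohorts. Oracle
checks (exposure minute-scan, pairwise AUC, exhaustive cutoff, fixture
Charlson) are exact. Newton fits converge to gradient max-norm below
1e-6; AUC oracle agreement is asserted to 1e-12.

## Known limitations

* The per-occurrence counting rule (a block counted once per calendar
  occurrence, fully on any overlap) is one reading of the exposure
  design; a capped or fractional-occupancy variant would change
  long-stay behaviour.
* Age enters linearly although a log-linear transform fits mortality
  better; kept for comparability with the model family's variable
  counts.
* Trajectories are unconditional profiles, not survival-conditioned
  forecasts.
* AIC/BIC comparisons inherit the usual caveat at large n: they tend to
  prefer larger models, and the family's information criteria rise with
  complexity even as discrimination improves.
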