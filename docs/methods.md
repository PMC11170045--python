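# Methods

`trialcea` implements a trial-based cost-effectiveness analysis of a guided
digital mental health intervention (Step-by-Step, "SbS") against enhanced
usual care ("EUC") in a two-arm randomized trial with assessments at
baseline (t0), week 8 (t1) and week 20 (t2), and ships a calibrated
synthetic-trial generator so that every stage of the analysis can be tested
against known ground truth.

## Costing

Resource use is recorded over the last 4 weeks before each assessment.
Unit prices (US $, 2019 price level, Lebanon) are shipped as a CSV table;
where a public and a private tariff exist, the mean price is their midpoint
and the table validates this at build time (tolerance $0.011, the rounding
grain of 2-decimal prices). Wage strata for productivity losses follow
nationality: Syrian $16.66/day, Lebanese $47.51/day, mixed mean $32.09/day;
homemakers' lost days are valued at the unpaid-work opportunity cost
($7.82/day); students, unemployed and retired participants accrue no
productivity cost (a conservative choice — the human-capital approach has
no standard valuation for them).

Two perspectives: *healthcare* counts direct medical items only
(primary/outpatient/inpatient care, emergency, medication DDDs); *societal*
adds absenteeism and presenteeism days valued at the stratum wage
(human-capital approach, no friction period). By construction the societal
minus healthcare cost equals the productivity cost exactly, per
participant-period.

**20-week accumulation.** Period costs cover 4-week windows; the horizon
spans five such periods (two between t0 and t1, three between t1 and t2).
Linear interpolation of the cost rate between assessments (trapezoid rule)
gives

```
cumulative = (c0+c1)/2 * 2 + (c1+c2)/2 * 3 = c0 + 2.5*c1 + 1.5*c2.
```

This convention reproduces the published cumulative means of the motivating
trial from its rounded period means to within $3 in all six
arm-by-category cells, which is the accuracy attainable without the
unrounded microdata.

The per-user intervention cost is the annual operating budget over annual
capacity: $122,320 / 4,700 = $26.03, added once to every SbS participant's
cumulative cost under both perspectives. The comparator's one-off
psychoeducational message (≈ $0.01) is ignored.

## Endpoints

PHQ-9 (0–27) is converted to two binary endpoints at t2: **response**
(≥ 50% improvement from t0; ties at exactly 50% count as response — the
integer-exact rule `2*t2 <= t0`) and **remission** (t2 score strictly
below 5). Endpoints are computed only after imputation of PHQ-9 scores,
never imputed directly. Eligibility requires age ≥ 18, PHQ-9 > 10 and
WHODAS-12 > 16 (strict inequalities), residence/language/internet access,
and no imminent suicide risk.

## Missing data

Dropout is severe in digital self-help trials (here ~63% overall at t2),
so the imputation stage is load-bearing. Targets are the PHQ-9 score and
the two aggregate period costs (healthcare, productivity) at t1 and t2;
costs are imputed at the aggregate level, not per resource item.
Predictors combine outcome predictors (baseline societal cost, PHQ-9,
gender, age, education, WHO-5) and missingness predictors (arm,
marital status, employment, baseline WHODAS-12), one-hot encoded with an
intercept.

* **Base case — regression imputation**: a single OLS fit per target on
  its complete cases; missing cells get the fitted conditional mean, with
  no residual draw. Deterministic by design: same input, same output.
  PHQ-9 imputations are rounded and clipped to 0–27 so endpoint conversion
  stays on the instrument scale. Cost imputations are *not* floored at
  zero: predictions for the zero-cost employment strata fall symmetrically
  around zero, and truncating them would lift the cheaper arm
  asymmetrically and bias the arm contrast (we measured a +$15 bias on the
  societal increment with flooring).
* **Sensitivity — MICE with predictive mean matching**: m = 20 completed
  datasets (config-exposed), 10 chained sweeps over the targets in time
  order (t1 before t2), each conditional model using the shared predictors
  plus the other targets at current values. Every imputed cell is an
  observed donor value, drawn uniformly among the k = 5 complete cases
  with the closest predicted means. m, k and the sweep count are common
  practice, not estimates.

## Estimation and inference

The cost and effect equations form a two-equation SUR system estimated by
feasible GLS with one iteration over the cross-equation residual
covariance: cost = intercept + arm + baseline period cost (adjusting for
chance baseline cost imbalance), endpoint = intercept + arm (a linear
probability model, so the arm coefficient is the absolute risk
difference). With identical regressors in both equations FGLS collapses to
OLS (the classical identity), which the tests exploit as an oracle,
alongside a dense Kronecker GLS solve on a 6-participant fixture.

Cost data are heavily skewed, so no normal-theory inference is attempted.
Uncertainty comes from a nonparametric participant bootstrap, stratified
by arm to preserve the randomization ratio (B = 2500 by default). In the
base case the regression imputation is **re-fitted inside every
resample**: with ~60% of follow-up cells imputed to conditional means,
freezing them and resampling the completed data would shrink the bootstrap
variance by roughly the squared observed-data share (we measured 44% CI
coverage of a known truth under that scheme, against 96% with
re-imputation). Re-imputation costs microseconds per replicate because the
design matrix is prebuilt. For MICE, the full bootstrap runs on each of
the m completed datasets and the m clouds are concatenated, so
between-imputation variance enters the cloud; the point estimate is the
mean over the m per-dataset fits. Degenerate resamples (constant endpoint,
rank loss) are redrawn and counted.

Decision analytics operate on the cloud of paired draws (ΔC_b, ΔE_b):
ICER = ΔC/ΔE with dominance classification ("dominant" when ΔC < 0 and
ΔE > 0, "dominated" for the reverse; ΔE = 0 yields a flagged undefined
value, not an exception); cost-effectiveness plane quadrant shares (ties:
ΔE = 0 counts East, ΔC = 0 counts South, so shares sum to 1 exactly and
CEAC(0) equals the SW+SE share identically); CEAC(λ) = P(λ·ΔE_b − ΔC_b ≥ 0)
over a WTP grid (defaults: $0–500 step 1 for response, $0–1500 for
remission); and WTP-at-probability queries by linear interpolation, with
"unattained" returned when the curve never reaches the requested level and
the first crossing (with a logged warning) on non-monotone curves. The
effect equation is arm-only by default (config-switchable covariates).

## Synthetic-trial generator

The generator emulates the structure the analysis assumes, with identical
baseline distributions across arms (randomization) and arm differences
confined to follow-up:

* **Sample**: 614/635 allocation; age ~ truncated normal (≥18, mean 29.1);
  gender, nationality, marital status, education and employment drawn from
  the trial's baseline table; wage stratum follows nationality.
* **Baseline scores**: PHQ-9 as a discretized normal truncated strictly
  above 10 (μ = 15.64, σ = 4 ⇒ mean 16.4 — σ is a calibration choice, the
  source reports no SD); WHODAS-12 truncated normal above 16 (mean 33.0,
  σ = 8); WHO-5 truncated normal on 0–100 (mean 30, σ = 14).
* **Follow-up PHQ-9**: a two-component mixture. A small "fully remitted"
  class (score ~ discretized N(2.0, 1.5); probability 5.5% EUC, 1.3% SbS)
  captures the tail that reaches remission outright; everyone else follows
  a latent linear model `0.355*phq0 + β_arm + 0.15*(whodas−33)
  − 0.12*(who5−30) + ε`, ε ~ N(0, 1.15²), rounded and clipped to 0–27,
  with β = 2.98 (EUC) vs 1.42 (SbS). t1 sits 40% of the way along the
  expected t0→t2 path. These constants were solved (by enumeration of the
  discrete baseline support and deterministic quadrature over the
  continuous covariates) so that the true response increment is 0.228 and
  the true remission increment 0.058, and so that the conditional mean is
  linear in the imputation model's predictors — the MAR analysis is
  consistent by construction, which is what a parameter-recovery oracle
  requires.
* **Costs**: each resource item is zero-inflated — Bernoulli use times a
  gamma amount — with use probabilities and cost shares fixed per item and
  the gamma scale solved from the cell's target mean. Per-arm period cost
  mean targets equal the motivating trial's published period means at
  baseline (pooled, since randomized arms share one baseline distribution)
  and are calibrated at follow-up so the true cumulative increments are
  +$28.0 (healthcare, including the $26.03 intervention cost) and −$24.0
  (societal). Gamma shapes (1.8 healthcare items, 1.3 lost workdays) were
  calibrated by simulation at the trial's size and dropout so that the
  sampling SDs of the incremental-cost estimators match the published
  bootstrap SEs ($25.44 healthcare, $31.15 societal). Amounts are
  continuous rather than integer counts, keeping the generator's expected
  increments closed-form.
* **Dropout**: logistic missing-at-random models per arm with slope 0.10
  on baseline PHQ-9 (sicker participants drop out more), intercepts solved
  by root-finding so the expected missingness matches the observed rates
  (t1: 64.2%/51.5%; t2: 68.1%/58.3%, SbS/EUC), and monotone missingness
  (lost at t1 ⇒ lost at t2).

`expected_increments` returns the generator's true (ΔC, ΔE) without any
random draws: cost increments are linear in the mean targets; endpoint
increments come from exact enumeration of the PHQ-9 support combined with
160-node Gauss–Legendre quadrature over the WHODAS/WHO-5 contribution.

**What the generator does not emulate.** Costs are independent of symptom
severity given the arm; real cost–severity correlation would make the MAR
assumption heavier-duty than it is here. Resource-use amounts are
continuous. Follow-up WHODAS/WHO-5 are noise around baseline, with no
treatment effect. Passing tests therefore demonstrate that the pipeline
recovers truth *when its assumptions hold*, not that the assumptions hold
in any real dataset.

**Known estimator distortion, reproduced deliberately.** Deterministic
conditional-mean imputation of a score that is then thresholded
underestimates tail-event probabilities among dropouts. The generator's
design absorbs this for response (the recovery bias is +0.002), but
remission — a deep-tail event — remains distorted: the base-case pipeline
recovers ≈ 0.068 against a truth of 0.058, while donor-based MICE does not
truncate the tail. A matching base-case/sensitivity divergence on the
remission rate is visible in the motivating trial's own results.

## Problem sizes in tests and the acceptance script

Generator consistency is checked at 10⁵ participants per arm against the
closed form (3 Monte-Carlo SEs). Parameter recovery runs 50 replicate
trials at the study's size with B = 500 bootstrap draws per replicate.
The acceptance script averages incremental estimates over 200 replicate
trials (the single-trial Monte-Carlo SE of the cost increments is ~$25,
larger than the quantities themselves) and pools bootstrap clouds over 30
replicate analyses for the plane and CEAC quantities; pooled shares are
the generator's long-run answer and sit closer to 0.5 than any single
trial's typically sharper (and luckier) shares.

## Limitations

* The two-point FGLS step is not iterated to convergence (one iteration is
  the conventional SUR estimator and is what the oracle checks).
* The linear probability model can emit fitted probabilities outside
  [0, 1]; only the arm coefficient (a risk difference) is consumed.
* MICE results are pooled by concatenating clouds rather than Rubin's
  rules; decision inference here is probabilistic, not test-based.
* No discounting (20-week horizon), no QALYs, no friction-cost method,
  no currency conversion (the LBP 1507.50/US$ 2019 rate is metadata only).
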