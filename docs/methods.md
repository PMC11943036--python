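# Methods

This note records the model, the bookkeeping conventions, the design choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Estimand and design

The target quantity is the per-protocol contrast between two
treatment-timing strategies for definitive PDA closure after referral:
*early* (closure within days 0–4 of referral) and *late* (days 5–14), on the
45-day cumulative incidence of successful extubation, with follow-up and
eligibility anchored at referral (day 0).  Anchoring both arms at the same
time zero removes the immortal-time bias of naive comparisons that classify
infants by when they eventually underwent closure.

Because an infant's early history can be compatible with both strategies,
each eligible infant contributes one clone per strategy.  A clone is
censored at *deviation*: the day of closure when it precedes the window, or
the last window day (the grace-period deadline) when the subject is still
untreated there.  The selection this censoring induces is removed by inverse
probability weighting (below).  This identifies, for each arm, the regime
"follow the natural initiation process while it remains compatible with the
window; initiate at the deadline if still untreated" — the standard
estimable regime of the deadline-censoring scheme.  The forced-adherence
benchmark used throughout the tests instead draws the closure day uniformly
over the window.  The two regimes coincide only approximately; under the
package's calibrated presets the difference is within about one percentage
point at the reporting days (measured by Monte Carlo at 6×10⁵ draws), and
the benchmark module also exposes `regime="deadline"` so the exact estimand
can be simulated.

### Competing risk

Death before successful extubation is a competing event.  The main analysis
reports the **total effect**: deceased clones remain in the risk set,
event-free, through day 45 — operationally, never extubated.  The
**controlled direct effect** variant instead censors at death (the death-day
row is emitted for bookkeeping but flagged not-at-risk, since within a day
death is evaluated before the extubation attempt).  No additional weighting
for death-censoring is applied in the CDE variant; with treatment-independent
death hazards this is innocuous, otherwise the CDE should be read as a
censor-at-death sensitivity analysis, not a fully adjusted direct effect.
Loss to follow-up (retro-transfer after the procedure) is administrative
censoring without additional weighting; it is assumed non-informative given
treatment status.

## Bookkeeping conventions

* Whole days on the referral clock; closed intervals; windows `[w_s, w_e]`
  inclusive.  An intervention on day 4 is early, on day 5 late.
* The hazard at day t applies to the interval [t, t+1); cumulative incidence
  is reported at the end of day t: CI(t) = 1 − Π_{k≤t}(1 − h(k)).
* At most one event transition per subject-day, evaluated as death →
  extubation attempt → loss to follow-up → treatment initiation.  Closure on
  day t therefore shifts hazards from day t+1.
* Same-day precedence: outcome ≻ artificial censoring ≻ administrative
  censoring.  An extubation on the deadline day of a still-untreated clone
  counts as an event, not a deviation.
* Death or the outcome on or before a would-be deviation day cancels the
  deviation (death before the deadline precludes the outcome rather than
  deviating from the strategy); loss to follow-up cancels it only when
  strictly earlier, by the same precedence.
* Successful extubation: the first extubation episode not followed by
  reintubation within seven days, provided it falls inside the horizon and
  strictly precedes death and loss to follow-up.  When the seven-day
  confirmation window runs past the last observed day, the episode counts as
  a success if no reintubation was observed (optimistic truncation; flagged
  as a convention, not a claim about how any registry adjudicated it).

## Initiation model and weights

The treatment model is a pooled logistic hazard of initiation on day t given
no initiation before t, fitted on subject-days at risk of initiation (days
before any of outcome/death/loss to follow-up, up to the latest deadline),
with per-day indicator strata — greedily pooled so every stratum contains at
least one initiation and one non-initiation — plus the baseline adjustment
set: birth weight, gestational age, age at referral, sex, referral year,
prior pharmacotherapy (referral site only in a sensitivity analysis).  Only
baseline covariates enter; post-baseline adjustment is out of scope.

Weight construction is described in the README; three deliberate choices:

* **Event-day rows** carry the cumulative weight through the previous day:
  the outcome is ascertained before the day's censoring opportunity, so an
  event on a boundary day is kept at its pre-boundary weight.  Without this,
  hazard estimates at boundary days acquire an O(h·ĥ) distortion.
* **Stabilisation** multiplies by pre-window survival factors of a
  covariate-free (time-only) initiation model, applied as a deterministic
  function of (strategy, day).  This makes the stabilising factor a common
  scalar within every (strategy, day) stratum, so saturated-in-time point
  estimates are exactly unchanged — the property that pins down the
  construction.  A per-clone numerator (e.g. one that also stabilises the
  deadline-day factor) reweights deadline initiators against within-window
  initiators and measurably biases the marginal curves; it is therefore not
  used.  Default: unstabilised.
* **Truncation** caps weights at a percentile computed within
  (strategy, day) strata, so the structurally large deadline-day weights are
  not clipped wholesale.  The default is *no truncation*: under strongly
  confounded presets the top weights carry genuine covariate mass and a 99th
  percentile cap moves the arm curves by several percentage points.
  Truncation remains available (`truncation_pct=99.0`) as a
  variance-robustness option, and the weight table reports both raw and
  truncated columns with a truncation flag.

Predicted initiation probabilities of exactly 0 or 1 on a day where a weight
needs them raise a positivity error naming the offending days.

## Outcome model

Marginal weighted pooled logistic hazard: strategy, cubic polynomial in
t/45, and full strategy-by-time interactions (8 parameters for two arms);
a saturated per-(strategy, day) option is available, whose MLE is computed
directly as weighted event proportions (days without at-risk mass get hazard
0).  Rows flagged artificially censored, and not-at-risk death-day rows of
the CDE variant, are excluded from the risk set; administrative-censoring
day rows are included (the outcome is observed on those days under the
within-day ordering).  Model fits use an in-package deterministic
Newton–Raphson solver (zero start, step-halving, tolerance 1e-11 on the
step) for speed inside bootstrap loops; the test suite verifies agreement
with statsmodels GLM to 1e-6 and detects separation and collinearity
explicitly.

Mean ventilator days is Σ_{t=1}^{45}(1 − CI(t)), exact by construction from
the reported curve.  Baseline tables use inverted-CDF (type-1) weighted
quantiles throughout, for both weighted and unweighted columns.

Confidence bands are subject-level percentile bootstrap (clones of one
subject are dependent by construction, so resampling clones would be
anti-conservative); each replicate regenerates clones and refits both
models.  Replicates that fail to fit are skipped and counted; more than 10%
failures aborts.  The paper-style reporting of a bootstrap interval method
is a package choice — no particular interval method is canonical for this
design.

## Synthetic registry generator

The generator emulates a referral cohort loosely calibrated to published
marginals for this population: gestational age ≈ 24.6 ± 1.6 weeks
(truncated 22–29.9), birth weight ≈ 760 g with a 60 g/week gestational-age
gradient, age at referral log-normal with median ≈ 16 days, female fraction
0.45, referral years 2014–2023, prior pharmacotherapy 83%.  Hazards are
logistic in fixed-standardised covariates, so they are probabilities by
construction.  The loss-to-follow-up rate after intervention is not reported
for any real registry; it is exposed as `ltfu_hazard` (default 0.01/day;
0.005 in the confounded preset).

Presets (`pdatrial.get_preset`):

* `default` — moderate confounding, treated log-odds +1.0 on extubation.
* `confounded` — the estimator-stress preset: initiation hazard ≈ 0.24/day
  at the covariate centre declining ≈ 0.055 logits/day, birth-weight
  log-odds −0.6 on initiation and +0.9 on extubation, treated effect +0.7
  plus 0.02/day since treatment.  The initiation level and slope were chosen
  so the deadline-regime timing inside each grace window matches the
  uniform-adherence benchmark closely (mean-matched within each window),
  while the confounding still biases unweighted clone estimates by 6–16
  percentage points; the coefficient magnitudes also keep deadline weights
  moderate enough that finite-sample ratio bias of the weighted estimator
  stays inside the recovery tolerance at n = 2000.
* `null` — closure affects no hazard.  Designed as a precise diagnostic
  world: covariate-free initiation hazard rising with day (logit −1.5 +
  0.14·t), slow extubation course, no deaths, loss to follow-up or
  eligibility exclusions.  The cloned design's risk-difference noise is
  dominated by arm disjointness and deadline-weight spikes; this
  configuration minimises both, leaving a max-over-days noise floor of about
  1.5 percentage points at n = 5000 — the smallest spurious-effect bound a
  single run of this design can certify.
* `site_confounded` — referral site shifts both initiation and extubation
  hazards (for the adjustment-set sensitivity analysis).
* `paper_shape` — the default world at the scale of a single-institution
  cohort (131 referrals), for smoke tests at realistic size.

The forced-adherence oracle draws the closure day uniformly over the window
(or runs the deadline regime), disables loss to follow-up (the per-protocol
estimand assumes complete follow-up), applies the same eligibility screen,
and counts deaths as never extubated.  On the forced day the procedure is
not deferred by a same-day failed extubation attempt: the
one-transition-per-day rule describes the observational process, not the
counterfactual regime — without this the oracle and the weighted
pseudo-population differ by one to two percentage points at day 14.

### What the synthetic world does not capture

Covariates are conditionally Gaussian/log-normal with a single
birth-weight–gestation correlation; there are no echocardiographic
variables, no post-baseline confounders, no seasonal or site-level referral
dynamics, and reintubation is a single flag rather than ventilator
telemetry.  Passing tests therefore establish that the implementation
estimates what it claims under a correctly specified logistic world of
moderate dimension — not that the adjustment set suffices in any real
registry, where unmeasured confounding and informative retro-transfer
remain the dominant threats.

## Numerical choices and degenerate inputs

* Logistic fits: dense Newton with eigenvalue-based collinearity detection
  (condition number > 1e12 aborts with the column list) and a separation
  bound of 30 on standardised coefficients.
* Saturated hazards on empty strata are 0 (boundary MLE).
* Day strata of the initiation model pool forward until each stratum has an
  initiation and a non-initiation; a trailing incomplete stratum folds into
  its predecessor.
* Missing eligibility flags render a subject ineligible (tallied under
  `missing_flags`).
* Subjects whose age-axis window closed before referral, or beyond a
  strategy's age cap, are excluded before cloning with a logged reason.
* Problem sizes in the test suite (50 replicates × n = 2000 for parameter
  recovery; 100 registries × 100 bootstrap replicates at n = 500 for
  coverage; 6×10⁵-draw oracles) were chosen to bound Monte-Carlo error on
  each check well below its tolerance while keeping the default suite fast.

## Known limitations

* The uniform-within-window benchmark and the deadline-censoring estimand
  differ in principle; the presets keep the gap small, but analyses of other
  worlds should benchmark against `regime="deadline"`.
* The CDE variant does not re-weight for death censoring.
* Only one intervention per subject is supported; no continuous-time
  censoring; no doubly robust or targeted estimators.
* The bootstrap is percentile-only; at very small cohort sizes (n ≈ 131)
  intervals are wide and replicate failures more common.
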