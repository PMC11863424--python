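# Methods

## The analysis model

The package studies three concurrent lifestyle exposures — sleep duration
(hours/day), moderate-to-vigorous physical activity (MVPA, min/day) and a
diet quality score (DQS, points on 0–100) — and their joint association
with all-cause mortality under Cox proportional hazards.

Two model forms are fitted on the prepared analysis sample:

* **Joint tertile model.** Each Winsorized exposure is cut at its
  33.33/66.67 sample percentiles into low/medium/high; the cross of the
  three tertiles yields 27 mutually exclusive cells, entered as a single
  categorical term with the all-low cell as referent (26 coefficients),
  plus linear covariates. Per-cell hazard ratios with Wald 95% intervals
  are exported as a 27-row table.
* **Continuous additive model.** Each exposure enters as a restricted
  cubic spline (Harrell truncated-power basis, linear tails) with 3 knots
  at its 10th/50th/90th percentiles; no exposure-by-exposure interaction
  terms, so predictions factor additively on the log-hazard scale. A
  hazard ratio between any two exposure points is exp(c'β) for the basis
  contrast c, with a delta-method (Wald) interval from the coefficient
  covariance.

Partial-likelihood maximisation uses the Efron approximation for tied
event times, a gradient tolerance of 1e-9 and at most 100 Newton steps;
non-convergence raises rather than warning. Proportionality is checked by
the score test on scaled Schoenfeld residuals against rank-transformed
time, per term, with a Bonferroni-combined global flag.

## Diet quality score

The DQS sums ten component scores, each 0 (unhealthiest) to 10
(healthiest): six healthy-high components (vegetables, fruits, fish,
dairy, whole grains, vegetable oils) and four reverse-scored healthy-low
components (refined grains, processed meats, unprocessed red meats,
sugar-sweetened beverages). Component scoring interpolates linearly
between two intake anchors and clamps; the anchors and units are data,
shipped as `data/dqs_scales.yaml` and overridable. Defaults follow the
healthy-diet-score convention for this questionnaire family (e.g.
vegetables 0 → 0 points, ≥3 servings/day → 10; sugary beverages 0 → 10,
≥1/day → 0); processed meats are anchored over 0–2 servings/week so a
1-serving/week reduction equals 5 points, matching the published
food-equivalent phrasing for this score. Linear (not binned) component
scoring was chosen because it makes score-increment ↔ food-change
translations (`dqs_increment_equivalents`) well defined and invertible;
increments above 10 points decompose greedily across components.
Missing components are a hard error — exclusion for incomplete data is an
upstream cohort-preparation concern, never silent imputation.

## Cohort preparation

* **Wear-time rule:** at least 3 days with > 16 h device wear, at least
  one a weekend day (Saturday/Sunday flag supplied per day record).
* **Exclusions** run in a fixed, logged order — unable-to-walk, missing
  covariates, death in the first follow-up year (reverse-causation
  guard), then optional sensitivity exclusions (poor health, prevalent
  CVD/cancer) — producing a per-reason count ledger that sums exactly to
  the rows removed.
* **Winsorization** clamps each exposure at its 2.5/97.5 sample
  percentiles (`mode="exclude"` trims instead, for sensitivity use).
  Percentiles are linear-interpolation (type-7) quantiles, stated here
  because tertile boundaries are sensitive to the convention. Tertiles are
  computed after Winsorization.
* **Tertile intervals** are half-open [lo, hi) with the top interval
  closed, so the three printed ranges tile the Winsorized range and a
  value on a boundary belongs to the upper category.

## Dose-response grid and minimal combined dose

Reference anchors: the combined 5th percentile of all three exposures
("unhealthy"), the medians ("healthy"), or guideline values (7 h/day
sleep, 20 min/day MVPA ≈ 150 min/week, and — lacking a DQS guideline —
the 25th-percentile score). The dose grid evaluates the continuous model
at percentile-derived axis values (levels 10/30/50/70/90, rounded to
multiples of 5 *before* mapping to exposure units) against the anchor.

The minimum combined dose for a target reduction t is the first point on
the equal-percentile diagonal — all three exposures advanced through the
same population percentile from the anchor, in 0.1-percentile steps —
whose predicted HR ≤ 1 − t/100. The diagonal was chosen as the scalar
ordering of 3-D increments because published combined-dose ladders
advance all behaviours in lock-step; a combination-matrix mode
(`dose_combinations`) returns every grid point within tolerance of a
target for heatmap-style views. Per-exposure minimal doses scan a fine
grid (sleep 1 min/day, MVPA 0.1 min/day, DQS 0.5 points) with the other
two exposures fixed at their medians, and report "unreachable" when the
whole in-range scan stays above the threshold — no extrapolation beyond
the Winsorized range is ever used. Ties along the path cannot arise
(the first crossing is unique by construction of a monotone scan), and
the location of the minimal dose deliberately carries no interval: only
the HR at it does.

## Additive interaction

RERI = rr₁₁ − rr₁₀ − rr₀₁ + 1, AP = RERI/rr₁₁,
S = (rr₁₁ − 1)/((rr₁₀ − 1) + (rr₀₁ − 1)); the three-exposure versions use
+2 and the sum of the three single-exposure excess risks. Inputs are the
corner hazard ratios of the dichotomised exposure cross (default: high
tertile vs rest, configurable), taken from a Cox model with one indicator
per non-referent corner cell. CIs use the delta method on the log-HR
covariance (log-scale for S, Hosmer–Lemeshow style); a seeded parametric
bootstrap (default 2,000 resamples) is available as a cross-check. S with
a zero excess-risk denominator is returned as a typed "undefined" state
so pipelines fail loudly; the log-S interval is additionally undefined
when rr₁₁ ≤ 1 or the denominator is negative (the point estimate is still
reported).

## Synthetic cohort generator

The generator emulates the *statistical shape* of a large wearables
cohort, not any particular dataset:

* **Exposure marginals** — sleep ~ truncated normal (mean 7.6, sd 1.0 h,
  bounds 3–12), MVPA ~ log-normal (log-median 3.44 ⇒ median ≈ 31 min/day,
  log-sd 0.72 chosen to reproduce a ~18–49 interquartile range), DQS ~
  truncated normal (mean 54.3, sd 9, bounds 0–100) — targeting medians of
  ≈ 7.6 h/day, ≈ 31 min/day and ≈ 54 points.
* **Dependence** — a Gaussian copula with a configurable correlation
  matrix (default modest positive correlations 0.10–0.15, reflecting the
  behavioural clustering of the three exposures) preserves the marginals
  exactly.
* **Covariates** — age (truncated normal, median ≈ 64), sex
  (Bernoulli 0.454 male) and one generic standard-normal confounder.
  The full covariate list of a real analysis is supported as pass-through
  columns; simulating each individually adds nothing to what the
  adjustment machinery tests.
* **Outcome** — Weibull baseline (shape 1.1; scale 146 years calibrated
  to ≈ 4% event probability over 8 years for an average participant) with
  a log-linear (optionally interacting) exposure effect; exposures and
  covariates are centered at their population centers before entering the
  linear predictor so the baseline stays interpretable. Event times are
  inverse-transform samples; censoring is the minimum of administrative
  follow-up (8 years) and exponential dropout with per-year probability
  `censor_rate` (rate −log(1−p); p = 1 degenerates to immediate
  censoring).
* **FFQ generation** — given per-participant DQS targets, the 0–100 total
  is split across the ten components by sequential random allocation
  within feasibility bounds and inverted through the linear scales, so
  rescoring recovers the target exactly.
* **Seeding** — one integer seed fans out via `SeedSequence.spawn` into
  independent substreams (exposures, FFQ, event times, censoring), so
  stages are reproducible in isolation.

What the generator does **not** emulate: accelerometer measurement error,
the seasonal/diurnal structure of wear data, FFQ reporting bias, the
selection process of a volunteer cohort, and real covariate–exposure
confounding patterns. Passing tests therefore demonstrate that the
*estimators* are correct under a proportional-hazards data-generating
process with known truth — not that any particular epidemiological
finding generalises.

## Test and simulation scale

Deterministic properties (score bounds, cell structure, closed-form HR
contrasts, minimal-dose crossings against an analytic surface) run on
constructed inputs. Stochastic calibration uses 200 replicates of n = 5,000
for coefficient recovery/CI coverage (baseline scale 100 in that study so
every replicate carries ≥ 200 events) and 200 replicates for the
additive-interaction null (constant-hazard truth h₀(1 + z₁ + z₂), which
makes excess hazard ratios exactly additive by construction). Parameter
recovery asserts |bias| < 0.25·SE and coverage within [92%, 98%];
null-interaction coverage is asserted within a 2σ binomial band around
95%. Larger cohorts (n = 50,000) are used once for marginal/copula
convergence checks.

## Known limitations

* Absolute risks per 10,000 person-years are crude (unadjusted) per
  group, with exact Poisson intervals; no model-standardised variant is
  currently computed.
* The continuous model is additive by design; if the true surface has
  strong exposure interactions, the minimal-dose ladder inherits the
  additive approximation (the joint tertile model and RERI machinery are
  the tools that surface such interaction).
* `check_ph` needs the live fitted model; a fit deserialised from JSON
  retains coefficients and predictions but not residual-level checks.
* The equal-percentile diagonal is one of many defensible scalarisations
  of "smallest combined increment"; results at a given target should be
  read together with the combination-matrix view.
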