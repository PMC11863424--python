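# span-mortality

Joint modelling of three lifestyle behaviours — **S**leep, **P**hysical
**A**ctivity and **N**utrition (SPAN) — in relation to all-cause mortality.

Large cohort studies usually analyse sleep duration, moderate-to-vigorous
physical activity (MVPA) and diet quality one behaviour at a time. This
package implements the combined-exposure analysis for epidemiologists who
want to ask the joint questions instead: *which combination of the three
behaviours carries the lowest mortality risk*, and *what is the smallest
simultaneous improvement in all three associated with a clinically
meaningful (e.g. 10%) risk reduction*. Because the motivating cohort data
(wrist-accelerometer sleep/MVPA plus food-frequency diet scores) are
access-restricted, the package ships a synthetic-cohort generator with the
same statistical structure, so every stage is runnable and testable
end-to-end without any download.

## What it computes

Exposures are sleep (hours/day), MVPA (min/day) and a 10-component diet
quality score, DQS ∈ [0, 100] (each food/beverage category scored 0–10,
higher = healthier). After Winsorizing each exposure at its 2.5/97.5
percentiles, two Cox proportional-hazards models are fitted with
covariate adjustment:

1. **Joint tertile model** — a single categorical joint exposure with the
   27 cells of (sleep, MVPA, DQS) tertiles, hazard ratios
   h(t|cell)/h(t|all-low referent);
2. **Continuous additive model** — restricted cubic splines
   (3 knots, 10th/50th/90th percentiles) for each exposure as independent
   terms: log h(t|x) = log h₀(t) + f₁(sleep) + f₂(MVPA) + f₃(DQS) + γ'z.

From the continuous fit the package builds the combined-dose HR grid
against the combined 5th-percentile anchor and searches the
equal-percentile path for the **minimum combined dose**: the smallest
lock-step increase in all three behaviours with predicted
HR ≤ 1 − target/100 for each target 10–70%. Additive interaction between
behaviours is quantified by RERI (= rr₁₁ − rr₁₀ − rr₀₁ + 1), the
attributable proportion AP = RERI/rr₁₁ and the synergy index
S = (rr₁₁ − 1)/((rr₁₀ − 1) + (rr₀₁ − 1)), with delta-method or bootstrap
intervals, including the three-exposure extension.

## Worked example

```python
import span_mortality as sm
from span_mortality import cohort_prep, survival, dose_response

cfg = sm.SyntheticCohortConfig(n_participants=20_000, seed=42)
cohort = sm.generate_cohort(cfg)
cohort, _ = cohort_prep.apply_exclusions(
    cohort, {"death_in_first_year": True},
    covariate_cols=["age", "sex", "confounder"],
)
for e in survival.EXPOSURES:
    cohort[e] = cohort_prep.winsorize(cohort[e].to_numpy()).values
cuts = {e: cohort_prep.tertile_cuts(cohort[e], name=e) for e in survival.EXPOSURES}
cohort = cohort_prep.assign_joint_categories(
    cohort, cuts["sleep"], cuts["mvpa"], cuts["dqs"])

fit = survival.fit_continuous_model(
    cohort, covariate_cols=("age", "sex", "confounder"))
anchor = dose_response.anchor_from_percentile(cohort, 5.0)
ladder = dose_response.minimal_dose_ladder(
    fit, anchor, targets=(10, 30, 50), include_individual=False)
print(ladder.round(2))
```

Output (the anchor here is sleep 5.9 h/day, MVPA 9.6 min/day, DQS 39.1 —
the combined 5th percentile of this simulated cohort):

```
 target_reduction_pct  reached  delta_sleep_min  delta_mvpa_min  delta_dqs_points  hr  ci_lo  ci_hi
                   10     True            24.48            3.27              3.82 0.9   0.81   0.99
                   30     True            75.00           13.62             11.42 0.7   0.53   0.93
                   50     True           124.53           32.89             19.06 0.5   0.35   0.71
```

Read row one as: relative to a person at the unhealthy (5th-percentile)
anchor, the model associates ~24 extra minutes of sleep, ~3 extra minutes
of MVPA and ~4 extra DQS points *together* with a 10% lower mortality
hazard (HR 0.90, 95% CI 0.81–0.99). A DQS increment translates into food
changes via `sm.dqs_increment_equivalents` (e.g. 5 points ≈ half a scale
step on one component, such as 1 less processed-meat serving per week).
The 27-cell joint model on the same cohort identifies the lowest-risk
tertile combination (here high MVPA, high sleep, medium DQS, HR 0.31,
95% CI 0.17–0.56 vs the all-low referent).

The full pipeline — simulate/load, score, prepare, fit, dose grids,
interaction indices, CSV/JSON exports and a reproducibility manifest — is
one command:

```bash
span all --seed 42 --out results/
```

## Layout

- `src/span_mortality/diet_score.py` — 100-point DQS, scale file, food-change equivalents
- `src/span_mortality/simulate.py` — synthetic cohorts (Gaussian-copula exposures, Weibull PH outcome)
- `src/span_mortality/cohort_prep.py` — wear-time filter, exclusions, Winsorization, 27-cell joint tertiles
- `src/span_mortality/survival.py` — Cox model forms, HR contrasts, Schoenfeld PH check, absolute risk
- `src/span_mortality/dose_response.py` — dose grids, per-exposure and combined minimal doses
- `src/span_mortality/interaction.py` — RERI / AP / S with delta-method and bootstrap CIs
- `src/span_mortality/pipeline.py`, `cli.py` — orchestration and the `span` command
- `docs/methods.md` — model and design notes
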