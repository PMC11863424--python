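"""Synthetic SPAN cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: sleep (hours/day, truncated normal), MVPA (minutes/day,
log-normal) and DQS (points, truncated normal on [0, 100]) joined by a
Gaussian copula with a configurable correlation matrix; simple covariates
(age, sex, one generic confounder); FFQ category frequencies consistent
with a target DQS; and survival times drawn from a Weibull
proportional-hazards model with independent censoring.

Defaults emulate the exposure marginals of a large UK accelerometry cohort
(median sleep ~7.6 h/day, MVPA ~31 min/day, DQS ~54) and an event rate of
roughly 4% over 8 years of follow-up.  A single integer seed fans out into
independent substreams (exposures, FFQ, survival, censoring) so each stage
is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .diet_score import (
    DQS_COMPONENTS,
    HEALTHY_HIGH,
    ComponentScale,
    default_scales,
)

__all__ = [
    "SyntheticCohortConfig",
    "TrueHazardModel",
    "generate_exposures",
    "generate_ffq",
    "simulate_survival",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "write_config",
    "read_config",
]

_DEFAULT_CORR = ((1.0, 0.15, 0.10), (0.15, 1.0, 0.15), (0.10, 0.15, 1.0))

# Truncation bounds for the exposure marginals (physically plausible ranges).
_SLEEP_BOUNDS = (3.0, 12.0)
_DQS_BOUNDS = (0.0, 100.0)
_AGE_BOUNDS = (43.0, 80.0)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort size, exposure marginals, censoring and baseline hazard.

    Exposure defaults target medians of ~7.6 h/day sleep, ~31 min/day MVPA
    and ~54 DQS points.  ``censor_rate`` is the per-year dropout
    probability (converted internally to an exponential dropout rate);
    administrative censoring applies at ``censor_admin_years``.  The
    baseline hazard is Weibull with cumulative hazard (t/scale)^shape; the
    default scale is calibrated so an average participant has ~4% event
    probability over 8 years.
    """

    n_participants: int = 10_000
    seed: int = 0
    sleep_mean_h: float = 7.6
    sleep_sd_h: float = 1.0
    mvpa_log_mean: float = float(np.log(31.26))
    mvpa_log_sd: float = 0.72
    dqs_mean: float = 54.3
    dqs_sd: float = 9.0
    exposure_correlation: tuple = _DEFAULT_CORR
    censor_admin_years: float = 8.0
    censor_rate: float = 0.02
    baseline_hazard_scale: float = 146.0
    baseline_hazard_shape: float = 1.1

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("sleep_sd_h", "mvpa_log_sd", "dqs_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        R = np.asarray(self.exposure_correlation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("exposure_correlation must be a symmetric 3x3 matrix")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "exposure_correlation must be positive-definite"
            ) from exc

    @property
    def correlation(self) -> np.ndarray:
        return np.asarray(self.exposure_correlation, dtype=float)


@dataclass(frozen=True)
class TrueHazardModel:
    """Ground-truth log-hazard coefficients for simulation.

    Exposure betas are per unit of the raw exposure (per hour of sleep, per
    min/day of MVPA, per DQS point); ``interaction_terms`` maps pair/triple
    keys like ``"sleep:mvpa"`` (or ``"sleep:mvpa:dqs"``) to log-hazard
    coefficients on products of centered exposures, enabling synergistic or
    sub-additive structure.  With all betas zero the hazard is
    exposure-independent.
    """

    beta_sleep: float = 0.0
    beta_mvpa: float = 0.0
    beta_dqs: float = 0.0
    interaction_terms: Mapping[str, float] = field(default_factory=dict)
    covariate_betas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.beta_sleep, self.beta_mvpa, self.beta_dqs]
        vals += list(self.interaction_terms.values())
        vals += list(self.covariate_betas.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("all hazard-model coefficients must be finite")

    @classmethod
    def null(cls) -> "TrueHazardModel":
        return cls()

    @classmethod
    def protective_default(cls) -> "TrueHazardModel":
        """A realistic protective truth for end-to-end runs."""
        return cls(
            beta_sleep=-0.12,
            beta_mvpa=-0.012,
            beta_dqs=-0.008,
            covariate_betas={"age": 0.09, "sex": 0.45, "confounder": 0.25},
        )


def _streams(seed: int, n_streams: int = 4) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n_streams)
    return [np.random.default_rng(s) for s in children]


def _truncnorm(mean, sd, bounds):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def generate_exposures(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw the exposure table (sleep, mvpa, dqs) plus covariates.

    The three exposures are joined through a Gaussian copula with the
    configured correlation matrix; marginals are truncated normal (sleep,
    dqs) and log-normal (mvpa).  Covariates — age (truncated normal), sex
    (Bernoulli, 1 = male) and a standard-normal generic confounder — are
    drawn independently of the exposures.
    """
    rng = _streams(config.seed)[0]
    n = config.n_participants
    L = np.linalg.cholesky(config.correlation)
    z = rng.standard_normal((n, 3)) @ L.T
    u = stats.norm.cdf(z)
    sleep = _truncnorm(config.sleep_mean_h, config.sleep_sd_h, _SLEEP_BOUNDS).ppf(
        u[:, 0]
    )
    mvpa = np.exp(config.mvpa_log_mean + config.mvpa_log_sd * z[:, 1])
    dqs = _truncnorm(config.dqs_mean, config.dqs_sd, _DQS_BOUNDS).ppf(u[:, 2])
    age = _truncnorm(63.5, 5.8, _AGE_BOUNDS).ppf(rng.random(n))
    sex = (rng.random(n) < 0.454).astype(int)
    confounder = rng.standard_normal(n)
    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "sleep": sleep,
            "mvpa": mvpa,
            "dqs": dqs,
            "age": age,
            "sex": sex,
            "confounder": confounder,
        }
    )


def generate_ffq(
    dqs_targets,
    seed: int,
    scales: Mapping[str, ComponentScale] | None = None,
) -> pd.DataFrame:
    """FFQ component frequencies whose DQS equals the per-row target.

    For each participant, the target total is split across the 10
    components by sequential random allocation within feasibility bounds
    (each component can hold 0-10 points), then component scores are
    inverted to intakes through the linear scales, so rescoring with the
    same scales recovers the target exactly (continuous scale).
    """
    targets = np.asarray(dqs_targets, dtype=float)
    if np.any(targets < 0) or np.any(targets > 100) or np.any(~np.isfinite(targets)):
        raise ValueError("DQS targets must lie in [0, 100]")
    scales = scales or default_scales()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, k = len(targets), len(DQS_COMPONENTS)
    remaining = targets.copy()
    scores = np.empty((n, k))
    for j in range(k):
        rest_cap = 10.0 * (k - j - 1)
        if j == k - 1:
            s = remaining
        else:
            lo = np.maximum(0.0, remaining - rest_cap)
            hi = np.minimum(10.0, remaining)
            s = lo + rng.random(n) * (hi - lo)
        scores[:, j] = s
        remaining = remaining - s
    cols = {}
    for j, c in enumerate(DQS_COMPONENTS):
        sc = scales[c]
        frac = scores[:, j] / 10.0
        if sc.direction != HEALTHY_HIGH:
            frac = 1.0 - frac
        cols[c] = sc.anchor_lo + frac * (sc.anchor_hi - sc.anchor_lo)
    return pd.DataFrame(cols)


def _linear_predictor(
    exposures: pd.DataFrame,
    model: TrueHazardModel,
    config: SyntheticCohortConfig,
) -> np.ndarray:
    """Centered linear predictor so the baseline is an average participant."""
    centers = {
        "sleep": config.sleep_mean_h,
        "mvpa": float(np.exp(config.mvpa_log_mean)),
        "dqs": config.dqs_mean,
        "age": 63.5,
        "sex": 0.454,
        "confounder": 0.0,
    }
    c = {k: exposures[k].to_numpy(dtype=float) - v
         for k, v in centers.items() if k in exposures}
    lp = (
        model.beta_sleep * c["sleep"]
        + model.beta_mvpa * c["mvpa"]
        + model.beta_dqs * c["dqs"]
    )
    for key, beta in model.interaction_terms.items():
        term = np.ones(len(exposures))
        for name in key.split(":"):
            term = term * c[name]
        lp = lp + beta * term
    for name, beta in model.covariate_betas.items():
        lp = lp + beta * c[name]
    return lp


def simulate_survival(
    exposures: pd.DataFrame,
    model: TrueHazardModel,
    config: SyntheticCohortConfig,
) -> pd.DataFrame:
    """Attach follow-up time and event indicator to an exposure table.

    Event times are inverse-transform samples from the Weibull
    proportional-hazards model h(t|x) = h0(t) exp(lp(x)); censoring is the
    minimum of administrative follow-up and exponential dropout.
    """
    _, _, rng_t, rng_c = _streams(config.seed)
    n = len(exposures)
    lp = _linear_predictor(exposures, model, config)
    u = rng_t.random(n)
    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    if config.censor_rate <= 0:
        t_drop = np.full(n, np.inf)
    elif config.censor_rate >= 1:
        t_drop = np.full(n, 1e-6)
    else:
        rate = -np.log1p(-config.censor_rate)
        t_drop = rng_c.exponential(1.0 / rate, size=n)
    t_cens = np.minimum(config.censor_admin_years, t_drop)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    out = exposures.copy()
    out["followup_years"] = np.maximum(time, 1e-9)
    out["event"] = event
    return out


def generate_cohort(
    config: SyntheticCohortConfig,
    model: TrueHazardModel | None = None,
    with_ffq: bool = False,
) -> pd.DataFrame:
    """Exposures + (optionally) FFQ columns + simulated survival outcome.

    With ``with_ffq=True`` the returned frame carries the 10 FFQ component
    columns generated to match each participant's drawn DQS, so the diet
    scoring stage can be exercised end-to-end.
    """
    model = model if model is not None else TrueHazardModel.protective_default()
    exposures = generate_exposures(config)
    if with_ffq:
        ffq_seed = int(
            np.random.SeedSequence(config.seed).spawn(2)[1].generate_state(1)[0]
            % (2**31)
        )
        ffq = generate_ffq(exposures["dqs"].to_numpy(), seed=ffq_seed)
        exposures = pd.concat([exposures, ffq], axis=1)
    return simulate_survival(exposures, model, config)


# ---------------------------------------------------------------------------
# cohort / config round-trip


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV and validate core invariants."""
    df = pd.read_csv(path)
    required = {"sleep", "mvpa", "dqs", "followup_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be binary 0/1")
    if (df["followup_years"] <= 0).any():
        raise ValueError("followup_years must be > 0")
    if ((df["dqs"] < 0) | (df["dqs"] > 100)).any():
        raise ValueError("dqs must lie in [0, 100]")
    return df


def write_config(config: SyntheticCohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["exposure_correlation"] = [
        [float(x) for x in r]
        for r in np.asarray(d["exposure_correlation"], dtype=float)
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def read_config(path) -> SyntheticCohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["exposure_correlation"] = tuple(tuple(r) for r in d["exposure_correlation"])
    return SyntheticCohortConfig(**d)
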