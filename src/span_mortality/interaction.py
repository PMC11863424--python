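"""Additive interaction measures: RERI, AP and the synergy index S.

For two binary exposures with relative risks rr10, rr01 (single) and rr11
(joint), departure from additivity of excess risks is measured by

    RERI = rr11 - rr10 - rr01 + 1
    AP   = RERI / rr11
    S    = (rr11 - 1) / ((rr10 - 1) + (rr01 - 1))

RERI = 0, AP = 0 and S = 1 denote exact additivity (no additive
interaction).  The three-exposure extension replaces the +1 with +2 and
sums the three single-exposure excess risks.  Confidence intervals use the
delta method on the log-HR covariance (Hosmer-Lemeshow style, with log-S
handled on its own scale); a seeded parametric bootstrap is available as a
cross-check.  S is undefined when the summed single-exposure excess risks
are zero; that state is typed, never silently NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasureEstimate",
    "UndefinedMeasure",
    "InteractionResult",
    "reri2",
    "reri3",
    "joint_dichotomous_rrs",
    "interaction_table",
]

_Z = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MeasureEstimate:
    estimate: float
    ci_lo: float | None = None
    ci_hi: float | None = None


@dataclass(frozen=True)
class UndefinedMeasure:
    """A typed 'undefined' state (e.g. S with zero excess-risk denominator)."""

    reason: str


@dataclass(frozen=True)
class InteractionResult:
    reri: MeasureEstimate
    ap: MeasureEstimate
    s: MeasureEstimate | UndefinedMeasure
    rrs: dict[str, float]
    covariance: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in (("RERI", self.reri), ("AP", self.ap), ("S", self.s)):
            if isinstance(m, UndefinedMeasure):
                rows.append(
                    {"measure": name, "estimate": np.nan, "ci_lo": np.nan,
                     "ci_hi": np.nan, "note": f"undefined: {m.reason}"}
                )
            else:
                rows.append(
                    {"measure": name, "estimate": m.estimate, "ci_lo": m.ci_lo,
                     "ci_hi": m.ci_hi, "note": ""}
                )
        return pd.DataFrame(rows)


def _validate(rrs: Sequence[float], cov, k: int):
    rr = np.asarray(rrs, dtype=float)
    if np.any(rr <= 0) or np.any(~np.isfinite(rr)):
        raise ValueError("all relative risks must be positive and finite")
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (k, k):
            raise ValueError(f"covariance must be {k}x{k} (log-HR scale)")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
    return rr, cov


def _delta_ci(value: float, grad: np.ndarray, theta_cov: np.ndarray):
    se = float(np.sqrt(max(grad @ theta_cov @ grad, 0.0)))
    return value - _Z * se, value + _Z * se


def _log_s_ci(rr_joint, excess_sum, singles, cov):
    """Delta-method CI for S on the log scale; None when log-S is undefined."""
    if rr_joint <= 1 or excess_sum <= 0:
        return None, None
    # d logS / d log rr_i: joint term rr_joint/(rr_joint-1); singles -rr_i/sum
    grad = np.array([-r / excess_sum for r in singles] + [rr_joint / (rr_joint - 1)])
    log_s = np.log((rr_joint - 1) / excess_sum)
    lo, hi = _delta_ci(log_s, grad, cov)
    return float(np.exp(lo)), float(np.exp(hi))


def _bootstrap(log_rr: np.ndarray, cov: np.ndarray, fn, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(log_rr, cov, size=n_boot)
    vals = fn(np.exp(draws))
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return None, None
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def reri2(
    rr10: float,
    rr01: float,
    rr11: float,
    covariance=None,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> InteractionResult:
    """Two-exposure additive interaction from relative risks.

    ``covariance`` is the 3x3 covariance of (log rr10, log rr01, log rr11)
    from the fitted model; without it only point estimates are returned.
    ``method`` selects delta-method (default) or parametric-bootstrap CIs.
    """
    (rr10, rr01, rr11), cov = _validate((rr10, rr01, rr11), covariance, 3)
    reri = rr11 - rr10 - rr01 + 1.0
    ap = reri / rr11
    excess_sum = (rr10 - 1.0) + (rr01 - 1.0)
    rrs = {"rr10": rr10, "rr01": rr01, "rr11": rr11}

    if excess_sum == 0:
        s: MeasureEstimate | UndefinedMeasure = UndefinedMeasure(
            "sum of single-exposure excess risks is zero"
        )
    else:
        s_val = (rr11 - 1.0) / excess_sum
        s = MeasureEstimate(s_val)

    if cov is None:
        return InteractionResult(MeasureEstimate(reri), MeasureEstimate(ap), s, rrs)

    log_rr = np.log([rr10, rr01, rr11])
    if method == "delta":
        # gradients w.r.t. theta = log RRs; d rr/d log rr = rr
        g_reri = np.array([-rr10, -rr01, rr11])
        reri_lo, reri_hi = _delta_ci(reri, g_reri, cov)
        g_ap = np.array([-rr10 / rr11, -rr01 / rr11, (rr10 + rr01 - 1.0) / rr11])
        ap_lo, ap_hi = _delta_ci(ap, g_ap, cov)
        if isinstance(s, MeasureEstimate):
            s_lo, s_hi = _log_s_ci(rr11, excess_sum, [rr10, rr01], cov)
            s = MeasureEstimate(s.estimate, s_lo, s_hi)
    elif method == "bootstrap":
        reri_lo, reri_hi = _bootstrap(
            log_rr, cov, lambda r: r[:, 2] - r[:, 0] - r[:, 1] + 1, n_boot, seed
        )
        ap_lo, ap_hi = _bootstrap(
            log_rr, cov,
            lambda r: (r[:, 2] - r[:, 0] - r[:, 1] + 1) / r[:, 2], n_boot, seed
        )
        if isinstance(s, MeasureEstimate):
            s_lo, s_hi = _bootstrap(
                log_rr, cov,
                lambda r: np.where(
                    (r[:, 0] + r[:, 1] - 2) != 0,
                    (r[:, 2] - 1) / (r[:, 0] + r[:, 1] - 2),
                    np.nan,
                ),
                n_boot, seed,
            )
            s = MeasureEstimate(s.estimate, s_lo, s_hi)
    else:
        raise ValueError(f"method must be 'delta' or 'bootstrap', got {method!r}")
    return InteractionResult(
        MeasureEstimate(reri, reri_lo, reri_hi),
        MeasureEstimate(ap, ap_lo, ap_hi),
        s,
        rrs,
        cov,
    )


def reri3(
    rr100: float,
    rr010: float,
    rr001: float,
    rr111: float,
    covariance=None,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> InteractionResult:
    """Three-exposure additive interaction.

    RERI3 = rr111 - rr100 - rr010 - rr001 + 2; AP = RERI3/rr111;
    S = (rr111 - 1) / sum of the three single-exposure excess risks.
    ``covariance`` is 4x4 over (log rr100, log rr010, log rr001, log rr111).
    """
    (rr100, rr010, rr001, rr111), cov = _validate(
        (rr100, rr010, rr001, rr111), covariance, 4
    )
    singles = [rr100, rr010, rr001]
    reri = rr111 - sum(singles) + 2.0
    ap = reri / rr111
    excess_sum = sum(r - 1.0 for r in singles)
    rrs = {"rr100": rr100, "rr010": rr010, "rr001": rr001, "rr111": rr111}

    if excess_sum == 0:
        s: MeasureEstimate | UndefinedMeasure = UndefinedMeasure(
            "sum of single-exposure excess risks is zero"
        )
    else:
        s = MeasureEstimate((rr111 - 1.0) / excess_sum)

    if cov is None:
        return InteractionResult(MeasureEstimate(reri), MeasureEstimate(ap), s, rrs)

    log_rr = np.log([rr100, rr010, rr001, rr111])
    if method == "delta":
        g_reri = np.array([-rr100, -rr010, -rr001, rr111])
        reri_lo, reri_hi = _delta_ci(reri, g_reri, cov)
        g_ap = np.array(
            [-rr100 / rr111, -rr010 / rr111, -rr001 / rr111,
             (sum(singles) - 2.0) / rr111]
        )
        ap_lo, ap_hi = _delta_ci(ap, g_ap, cov)
        if isinstance(s, MeasureEstimate):
            s_lo, s_hi = _log_s_ci(rr111, excess_sum, singles, cov)
            s = MeasureEstimate(s.estimate, s_lo, s_hi)
    elif method == "bootstrap":
        reri_lo, reri_hi = _bootstrap(
            log_rr, cov,
            lambda r: r[:, 3] - r[:, 0] - r[:, 1] - r[:, 2] + 2, n_boot, seed
        )
        ap_lo, ap_hi = _bootstrap(
            log_rr, cov,
            lambda r: (r[:, 3] - r[:, 0] - r[:, 1] - r[:, 2] + 2) / r[:, 3],
            n_boot, seed,
        )
        if isinstance(s, MeasureEstimate):
            s_lo, s_hi = _bootstrap(
                log_rr, cov,
                lambda r: np.where(
                    (r[:, 0] + r[:, 1] + r[:, 2] - 3) != 0,
                    (r[:, 3] - 1) / (r[:, 0] + r[:, 1] + r[:, 2] - 3),
                    np.nan,
                ),
                n_boot, seed,
            )
            s = MeasureEstimate(s.estimate, s_lo, s_hi)
    else:
        raise ValueError(f"method must be 'delta' or 'bootstrap', got {method!r}")
    return InteractionResult(
        MeasureEstimate(reri, reri_lo, reri_hi),
        MeasureEstimate(ap, ap_lo, ap_hi),
        s,
        rrs,
        cov,
    )


def joint_dichotomous_rrs(
    cohort: pd.DataFrame,
    covariate_cols: Sequence[str] = (),
    high_rule: str = "high_tertile",
    duration_col: str = "followup_years",
    event_col: str = "event",
):
    """Corner hazard ratios of the dichotomised 3-exposure cross.

    Each behaviour is dichotomised (default: its 'high' tertile vs the
    rest, requiring tertile columns from ``assign_joint_categories``;
    ``'top_half'`` splits at the median instead), and a Cox model with one
    indicator per non-referent cell of the 2x2x2 cross is fitted.  Returns
    the four RRs feeding :func:`reri3` — (1,0,0), (0,1,0), (0,0,1),
    (1,1,1) vs (0,0,0) — and their 4x4 log-HR covariance.
    """
    from .survival import _run_cox

    if high_rule == "high_tertile":
        flags = {
            e: (cohort[f"{e}_tertile"] == "high").astype(int) for e in
            ("sleep", "mvpa", "dqs")
        }
    elif high_rule == "top_half":
        flags = {
            e: (cohort[e] > cohort[e].median()).astype(int)
            for e in ("sleep", "mvpa", "dqs")
        }
    else:
        raise ValueError(f"unknown high_rule {high_rule!r}")
    z1, z2, z3 = flags["sleep"], flags["mvpa"], flags["dqs"]
    cell = z1 * 4 + z2 * 2 + z3  # 0..7, referent 0
    design = pd.DataFrame(index=cohort.index)
    for c in range(1, 8):
        design[f"d{c}"] = (cell == c).astype(float)
    for cov in covariate_cols:
        design[cov] = cohort[cov].astype(float)
    design[duration_col] = cohort[duration_col]
    design[event_col] = cohort[event_col]
    cph = _run_cox(design, duration_col, event_col)
    wanted = ["d4", "d2", "d1", "d7"]  # (1,0,0), (0,1,0), (0,0,1), (1,1,1)
    beta = cph.params_[wanted].to_numpy()
    cov_m = cph.variance_matrix_.loc[wanted, wanted].to_numpy()
    rrs = dict(zip(("rr100", "rr010", "rr001", "rr111"), np.exp(beta)))
    return rrs, cov_m


def interaction_table(result: InteractionResult) -> pd.DataFrame:
    """Export-ready (measure, estimate, ci_lo, ci_hi) table."""
    return result.to_frame()
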