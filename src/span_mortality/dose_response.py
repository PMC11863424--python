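"""Combined-dose hazard-ratio grids and minimal-dose search.

Anchored at a reference point — by default the combined 5th percentile of
sleep, MVPA and DQS ("unhealthy" reference); median and guideline anchors
are also supported — this module builds the 3-D hazard-ratio grid over
percentile-derived exposure increments, finds per-exposure minimal doses
for a target risk reduction (other exposures held at their medians), and
runs the minimum-combined-dose search: the smallest simultaneous increase
of all three behaviours whose model-predicted HR meets a target reduction
(10%, 20%, ... 70%).

"Minimum combined dose" is operationalised as the first crossing along the
equal-percentile diagonal from the anchor: all three exposures are advanced
in lock-step through the same population percentile.  A combination-matrix
mode returning every grid point within tolerance of a target is retained
for heatmap-style views.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survival import EXPOSURES, HazardFit, HRPrediction, predict_hr

__all__ = [
    "ReferenceAnchor",
    "DoseGrid",
    "MinimalDoseResult",
    "anchor_from_percentile",
    "anchor_from_median",
    "guideline_anchor",
    "percentile_axis",
    "build_grid",
    "individual_minimal_dose",
    "combined_minimum_dose",
    "dose_combinations",
    "minimal_dose_ladder",
]

#: Fine-grid step per exposure for the per-exposure dose scan
#: (sleep in hours/day = 1 min; MVPA 0.1 min/day; DQS 0.5 points).
FINE_STEPS = {"sleep": 1.0 / 60.0, "mvpa": 0.1, "dqs": 0.5}


@dataclass(frozen=True)
class ReferenceAnchor:
    """The exposure point HRs are contrasted against."""

    kind: str  # fifth_percentile | median | guideline | custom
    sleep: float  # hours/day
    mvpa: float  # min/day
    dqs: float  # score points

    def as_dict(self) -> dict[str, float]:
        return {"sleep": self.sleep, "mvpa": self.mvpa, "dqs": self.dqs}


def _exposure_samples(fit: HazardFit, cohort: pd.DataFrame | None) -> dict:
    if cohort is not None:
        return {e: cohort[e].to_numpy(dtype=float) for e in EXPOSURES}
    if fit.exposure_values:
        return fit.exposure_values
    raise ValueError("no exposure sample available; pass a cohort")


def anchor_from_percentile(
    cohort: pd.DataFrame, pct: float = 5.0
) -> ReferenceAnchor:
    """Combined ``pct``-th percentile of the three exposures."""
    kind = "fifth_percentile" if pct == 5.0 else f"percentile_{pct:g}"
    q = {e: float(np.percentile(cohort[e], pct)) for e in EXPOSURES}
    return ReferenceAnchor(kind=kind, sleep=q["sleep"], mvpa=q["mvpa"], dqs=q["dqs"])


def anchor_from_median(cohort: pd.DataFrame) -> ReferenceAnchor:
    """'Healthy' reference: the median of each exposure."""
    q = {e: float(np.median(cohort[e])) for e in EXPOSURES}
    return ReferenceAnchor(kind="median", sleep=q["sleep"], mvpa=q["mvpa"], dqs=q["dqs"])


def guideline_anchor(
    sleep: float = 7.0, mvpa: float = 20.0, dqs: float = 47.5
) -> ReferenceAnchor:
    """Guideline-oriented reference: 7 h/day sleep, ~20 min/day MVPA
    (150 min/week), and — absent a DQS guideline — the 25th-percentile
    score of 47.5 points."""
    return ReferenceAnchor(kind="guideline", sleep=sleep, mvpa=mvpa, dqs=dqs)


def percentile_axis(
    values, levels: Sequence[float] = (10, 30, 50, 70, 90), round_to: int = 5
) -> np.ndarray:
    """Exposure values at percentile levels rounded to the nearest
    multiple of ``round_to`` (levels 10/30/50/70/90 by default)."""
    lv = round_to * np.round(np.asarray(levels, dtype=float) / round_to)
    axis = np.percentile(np.asarray(values, dtype=float), lv)
    if np.any(np.diff(axis) <= 0):
        axis = np.unique(axis)
    return axis


@dataclass
class DoseGrid:
    """HR surface over exposure increments relative to an anchor."""

    anchor: ReferenceAnchor
    sleep_axis: np.ndarray
    mvpa_axis: np.ndarray
    dqs_axis: np.ndarray
    hr: np.ndarray  # shape (len(sleep), len(mvpa), len(dqs))
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sleep, mvpa, dqs, hr, ci_lo, ci_hi)."""
        s, m, d = np.meshgrid(
            self.sleep_axis, self.mvpa_axis, self.dqs_axis, indexing="ij"
        )
        return pd.DataFrame(
            {
                "sleep": s.ravel(),
                "mvpa": m.ravel(),
                "dqs": d.ravel(),
                "hr": self.hr.ravel(),
                "ci_lo": self.ci_lo.ravel(),
                "ci_hi": self.ci_hi.ravel(),
            }
        )


@dataclass(frozen=True)
class MinimalDoseResult:
    """Smallest combined increment achieving a target risk reduction.

    Deltas are relative to the anchor: sleep in min/day, MVPA in min/day,
    DQS in points.  ``reached`` is False when no in-range combination
    attains the target; ``achieved`` then holds the best (lowest-HR) point
    on the search path.
    """

    target_reduction: float
    delta_sleep_min: float
    delta_mvpa_min: float
    delta_dqs_points: float
    achieved: HRPrediction
    reached: bool = True


def build_grid(
    fit: HazardFit,
    anchor: ReferenceAnchor,
    axes: Mapping[str, Sequence[float]] | None = None,
    cohort: pd.DataFrame | None = None,
) -> DoseGrid:
    """HR at every axis combination relative to the anchor.

    Default axes are the exposures' 10/30/50/70/90th percentiles (levels
    rounded to the nearest multiple of 5), with the anchor value prepended
    so the grid contains the identity cell (HR 1).
    """
    samples = _exposure_samples(fit, cohort)
    if axes is None:
        axes = {}
        for e in EXPOSURES:
            ax = percentile_axis(samples[e])
            a = getattr(anchor, e)
            ax = np.unique(np.concatenate([[a], ax[ax > a]]))
            axes[e] = ax
    sleep_ax = np.asarray(axes["sleep"], dtype=float)
    mvpa_ax = np.asarray(axes["mvpa"], dtype=float)
    dqs_ax = np.asarray(axes["dqs"], dtype=float)
    shape = (len(sleep_ax), len(mvpa_ax), len(dqs_ax))
    hr = np.empty(shape)
    lo = np.empty(shape)
    hi = np.empty(shape)
    ref = anchor.as_dict()
    for i, s in enumerate(sleep_ax):
        for j, m in enumerate(mvpa_ax):
            for k, d in enumerate(dqs_ax):
                p = predict_hr(fit, {"sleep": s, "mvpa": m, "dqs": d}, ref)
                hr[i, j, k], lo[i, j, k], hi[i, j, k] = p.hr, p.ci_lo, p.ci_hi
    return DoseGrid(anchor, sleep_ax, mvpa_ax, dqs_ax, hr, lo, hi)


def individual_minimal_dose(
    fit: HazardFit,
    exposure: str,
    target_reduction: float,
    anchor: ReferenceAnchor,
    others_fixed_at: Mapping[str, float] | None = None,
    cohort: pd.DataFrame | None = None,
    step: float | None = None,
) -> tuple[float | None, HRPrediction]:
    """Smallest single-exposure increment meeting a target reduction.

    The scanned exposure starts at its anchor value while the other two
    exposures sit at fixed values (their medians by default).  Scans a fine
    grid up to the Winsorized range top; returns ``(None, best)`` when the
    target is unreachable in isolation.
    """
    if not 0 <= target_reduction < 100:
        raise ValueError("target_reduction must lie in [0, 100)")
    samples = _exposure_samples(fit, cohort)
    if others_fixed_at is None:
        others_fixed_at = {
            e: float(np.median(samples[e])) for e in EXPOSURES if e != exposure
        }
    base = dict(others_fixed_at)
    base[exposure] = getattr(anchor, exposure)
    ref = dict(base)
    threshold = 1.0 - target_reduction / 100.0
    hi = fit.exposure_ranges[exposure][1]
    step = step or FINE_STEPS[exposure]
    deltas = np.arange(0.0, hi - base[exposure] + step / 2, step)
    best: HRPrediction | None = None
    for d in deltas:
        point = dict(base)
        point[exposure] = min(base[exposure] + d, hi)
        d = point[exposure] - base[exposure]
        p = predict_hr(fit, point, ref)
        if best is None or p.hr < best.hr:
            best = p
        if p.hr <= threshold:
            return float(d), p
    return None, best


def _path_points(
    samples: Mapping[str, np.ndarray], anchor_pct: float, step_pct: float
):
    """Equal-percentile path: all exposures at the same percentile level."""
    pcts = np.arange(anchor_pct, 100.0 + step_pct / 2, step_pct)
    pcts = np.minimum(pcts, 100.0)
    pts = {e: np.percentile(samples[e], pcts) for e in EXPOSURES}
    return pcts, pts


def combined_minimum_dose(
    fit: HazardFit,
    target_reduction: float,
    anchor: ReferenceAnchor,
    cohort: pd.DataFrame | None = None,
    anchor_pct: float = 5.0,
    step_pct: float = 0.1,
) -> MinimalDoseResult:
    """Minimum simultaneous SPAN increment meeting a target risk reduction.

    Advances all three exposures in lock-step along the equal-percentile
    path from ``anchor_pct`` (the anchor's percentile) upward in
    ``step_pct`` increments, and returns the first point whose predicted
    HR vs the anchor is <= 1 - target/100.  If no point on the path
    attains the target, the result carries the best achievable HR with
    ``reached=False``.
    """
    if not 0 <= target_reduction < 100:
        raise ValueError("target_reduction must lie in [0, 100)")
    samples = _exposure_samples(fit, cohort)
    threshold = 1.0 - target_reduction / 100.0
    ref = anchor.as_dict()
    pcts, pts = _path_points(samples, anchor_pct, step_pct)
    best: HRPrediction | None = None
    best_point = ref
    for i in range(len(pcts)):
        point = {e: float(pts[e][i]) for e in EXPOSURES}
        p = predict_hr(fit, point, ref)
        if best is None or p.hr < best.hr:
            best, best_point = p, point
        if p.hr <= threshold:
            return MinimalDoseResult(
                target_reduction=target_reduction,
                delta_sleep_min=(point["sleep"] - anchor.sleep) * 60.0,
                delta_mvpa_min=point["mvpa"] - anchor.mvpa,
                delta_dqs_points=point["dqs"] - anchor.dqs,
                achieved=p,
            )
    return MinimalDoseResult(
        target_reduction=target_reduction,
        delta_sleep_min=(best_point["sleep"] - anchor.sleep) * 60.0,
        delta_mvpa_min=best_point["mvpa"] - anchor.mvpa,
        delta_dqs_points=best_point["dqs"] - anchor.dqs,
        achieved=best,
        reached=False,
    )


def dose_combinations(
    fit: HazardFit,
    target_reduction: float,
    anchor: ReferenceAnchor,
    axes: Mapping[str, Sequence[float]] | None = None,
    cohort: pd.DataFrame | None = None,
    tol: float = 0.01,
) -> pd.DataFrame:
    """All grid combinations within ``tol`` of the target HR.

    The combination-matrix view: every (sleep, mvpa, dqs) grid point whose
    predicted HR lies within ``tol`` of 1 - target/100.
    """
    grid = build_grid(fit, anchor, axes=axes, cohort=cohort)
    frame = grid.to_frame()
    threshold = 1.0 - target_reduction / 100.0
    return frame[np.abs(frame["hr"] - threshold) <= tol].reset_index(drop=True)


def minimal_dose_ladder(
    fit: HazardFit,
    anchor: ReferenceAnchor,
    targets: Sequence[float] = (10, 20, 30, 40, 50, 60, 70),
    cohort: pd.DataFrame | None = None,
    include_individual: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """The combined-dose ladder: one row per target reduction.

    Combined columns give the minimum lock-step SPAN increments (sleep in
    min/day, MVPA min/day, DQS points) and the achieved HR with CI;
    individual columns give the per-exposure dose needed in isolation
    (others at their medians), NaN where unreachable.
    """
    rows = []
    for t in targets:
        r = combined_minimum_dose(fit, t, anchor, cohort=cohort, **kwargs)
        row = {
            "target_reduction_pct": t,
            "reached": r.reached,
            "delta_sleep_min": r.delta_sleep_min,
            "delta_mvpa_min": r.delta_mvpa_min,
            "delta_dqs_points": r.delta_dqs_points,
            "hr": r.achieved.hr,
            "ci_lo": r.achieved.ci_lo,
            "ci_hi": r.achieved.ci_hi,
        }
        if include_individual:
            for e in EXPOSURES:
                d, _ = individual_minimal_dose(fit, e, t, anchor, cohort=cohort)
                if d is None:
                    row[f"individual_{e}"] = np.nan
                else:
                    row[f"individual_{e}"] = d * 60.0 if e == "sleep" else d
        rows.append(row)
    return pd.DataFrame(rows)
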