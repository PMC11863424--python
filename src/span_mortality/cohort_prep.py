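"""Cohort inclusion/exclusion rules, Winsorization and joint tertiles.

Implements the analysis-sample construction used for joint SPAN exposure
modelling: a wear-time filter (>= 3 valid days of > 16 h wear, at least one
of them a weekend day), ordered exclusion rules with a count ledger,
2.5/97.5-percentile Winsorization of the continuous exposures, and the
27-cell cross of low/medium/high tertiles with the all-low cell as referent.

Conventions (documented because results are sensitive to them):

* percentiles use linear interpolation (numpy default, R type-7);
* tertile intervals are half-open ``[lo, hi)`` with the top interval closed,
  so the three ranges tile the Winsorized range contiguously;
* exclusions are applied in a fixed order (unable-to-walk -> missing
  covariates -> first-year deaths -> optional sensitivity flags) so ledgers
  are comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExposureTertiles",
    "JointExposureCategory",
    "WinsorResult",
    "EXCLUSION_ORDER",
    "TERTILE_LABELS",
    "wear_time_filter",
    "apply_exclusions",
    "winsorize",
    "tertile_cuts",
    "assign_tertile",
    "assign_joint_categories",
    "cell_index",
]

TERTILE_LABELS = ("low", "medium", "high")

#: Fixed application order of the exclusion flags.
EXCLUSION_ORDER = (
    "unable_to_walk",
    "missing_covariates",
    "death_in_first_year",
    "poor_health",
    "prevalent_cvd_cancer",
)


@dataclass(frozen=True)
class ExposureTertiles:
    """Interior tertile boundaries for one exposure."""

    name: str
    cut_lo: float
    cut_hi: float

    def __post_init__(self) -> None:
        if not self.cut_lo < self.cut_hi:
            raise ValueError(
                f"{self.name}: tertile cuts must satisfy cut_lo < cut_hi, "
                f"got {self.cut_lo} / {self.cut_hi}"
            )


@dataclass(frozen=True)
class JointExposureCategory:
    """One of the 27 joint (sleep, MVPA, DQS) tertile cells."""

    sleep_tertile: str
    mvpa_tertile: str
    dqs_tertile: str
    cell_index: int
    is_referent: bool


@dataclass(frozen=True)
class WinsorResult:
    values: np.ndarray
    lo_value: float
    hi_value: float
    n_clamped_lo: int
    n_clamped_hi: int


def wear_time_filter(
    records: pd.DataFrame,
    min_valid_days: int = 3,
    min_wear_hours: float = 16.0,
) -> set:
    """Participants meeting the device wear-time inclusion rule.

    A participant is included iff they have at least ``min_valid_days`` days
    with wear time strictly greater than ``min_wear_hours`` hours AND at
    least one of those valid days is a weekend day.

    ``records`` has one row per participant-day with columns
    ``participant_id``, ``wear_hours`` and ``is_weekend``.
    """
    req = {"participant_id", "wear_hours", "is_weekend"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"wear records missing columns: {sorted(missing)}")
    wear = records["wear_hours"].to_numpy(dtype=float)
    if np.any(wear < 0) or np.any(wear > 24):
        raise ValueError("wear_hours must lie in [0, 24]")
    valid = records[wear > min_wear_hours]
    if valid.empty:
        return set()
    g = valid.groupby("participant_id")["is_weekend"]
    ok = (g.size() >= min_valid_days) & g.any()
    return set(ok.index[ok])


def apply_exclusions(
    cohort: pd.DataFrame,
    flags: Mapping[str, bool],
    covariate_cols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the enabled exclusion rules in fixed order.

    Returns the filtered cohort and a ledger mapping each enabled flag to
    the number of rows it removed (in application order), supporting a
    participant-flow export.  Flag semantics:

    * ``unable_to_walk`` — drop rows where the boolean column of the same
      name is true;
    * ``missing_covariates`` — drop rows with any NaN among
      ``covariate_cols``;
    * ``death_in_first_year`` — drop rows with an event in the first year
      of follow-up (reverse-causation guard);
    * ``poor_health`` / ``prevalent_cvd_cancer`` — sensitivity exclusions
      keyed on the same-named boolean columns (``prevalent_cvd`` or
      ``prevalent_cancer`` for the latter).
    """
    unknown = set(flags) - set(EXCLUSION_ORDER)
    if unknown:
        raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
    out = cohort
    ledger: dict[str, int] = {}
    for flag in EXCLUSION_ORDER:
        if not flags.get(flag, False):
            continue
        if flag == "unable_to_walk":
            drop = out["unable_to_walk"].astype(bool)
        elif flag == "missing_covariates":
            cols = list(covariate_cols or [])
            if not cols:
                raise ValueError(
                    "missing_covariates exclusion requires covariate_cols"
                )
            drop = out[cols].isna().any(axis=1)
        elif flag == "death_in_first_year":
            drop = (out["event"] == 1) & (out["followup_years"] < 1.0)
        elif flag == "poor_health":
            drop = out["poor_health"].astype(bool)
        else:  # prevalent_cvd_cancer
            drop = (
                out["prevalent_cvd"].astype(bool)
                | out["prevalent_cancer"].astype(bool)
            )
        ledger[flag] = int(drop.sum())
        out = out[~drop]
    return out, ledger


def winsorize(
    values,
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
    mode: str = "clamp",
) -> WinsorResult:
    """Winsorize (or trim) an exposure vector at the given percentiles.

    ``mode='clamp'`` (default) sets values below the ``lo_pct`` percentile
    to that percentile and values above the ``hi_pct`` percentile to that
    percentile.  ``mode='exclude'`` drops the tail values instead — the
    sensitivity-analysis variant — so the output may be shorter than the
    input.  Percentiles are computed on the input sample itself with linear
    interpolation.
    """
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 2:
        raise ValueError("winsorize needs at least 2 finite values")
    if mode not in ("clamp", "exclude"):
        raise ValueError(f"mode must be 'clamp' or 'exclude', got {mode!r}")
    lo, hi = np.percentile(x, [lo_pct, hi_pct])
    if lo == hi:
        warnings.warn(
            "all values identical within the Winsorization band; "
            "returned unchanged",
            stacklevel=2,
        )
        return WinsorResult(x.copy(), float(lo), float(hi), 0, 0)
    below, above = x < lo, x > hi
    if mode == "clamp":
        out = np.clip(x, lo, hi)
    else:
        out = x[~(below | above)]
    return WinsorResult(
        out, float(lo), float(hi), int(below.sum()), int(above.sum())
    )


def tertile_cuts(values, name: str = "exposure") -> ExposureTertiles:
    """Interior tertile boundaries (33.33/66.67 sample percentiles)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"{name}: need at least 3 distinct values to form tertiles"
        )
    cut_lo, cut_hi = np.percentile(x, [100 / 3, 200 / 3])
    if cut_lo == cut_hi:
        raise ValueError(f"{name}: degenerate tertile cuts (ties at {cut_lo})")
    return ExposureTertiles(name=name, cut_lo=float(cut_lo), cut_hi=float(cut_hi))


def assign_tertile(values, cuts: ExposureTertiles) -> np.ndarray:
    """Map values to 'low'/'medium'/'high' with [lo, hi) intervals.

    The top interval is closed, so the maximum maps to 'high'.
    """
    x = np.asarray(values, dtype=float)
    idx = np.searchsorted([cuts.cut_lo, cuts.cut_hi], x, side="right")
    return np.asarray(TERTILE_LABELS, dtype=object)[idx]


def cell_index(sleep_t: str, mvpa_t: str, dqs_t: str) -> int:
    """1-based index of a joint tertile cell; (low, low, low) -> 1."""
    i = {lab: k for k, lab in enumerate(TERTILE_LABELS)}
    return 9 * i[sleep_t] + 3 * i[mvpa_t] + i[dqs_t] + 1


def assign_joint_categories(
    cohort: pd.DataFrame,
    sleep_cuts: ExposureTertiles,
    mvpa_cuts: ExposureTertiles,
    dqs_cuts: ExposureTertiles,
) -> pd.DataFrame:
    """Attach per-exposure tertiles and the 27-cell joint category.

    Adds columns ``sleep_tertile``, ``mvpa_tertile``, ``dqs_tertile``,
    ``cell_index`` (1..27) and ``is_referent`` (cell 1 = all-low).
    """
    out = cohort.copy()
    out["sleep_tertile"] = assign_tertile(out["sleep"], sleep_cuts)
    out["mvpa_tertile"] = assign_tertile(out["mvpa"], mvpa_cuts)
    out["dqs_tertile"] = assign_tertile(out["dqs"], dqs_cuts)
    i = {lab: k for k, lab in enumerate(TERTILE_LABELS)}
    out["cell_index"] = (
        9 * out["sleep_tertile"].map(i)
        + 3 * out["mvpa_tertile"].map(i)
        + out["dqs_tertile"].map(i)
        + 1
    )
    out["is_referent"] = out["cell_index"] == 1
    return out


def all_cells() -> list[JointExposureCategory]:
    """The full 27-cell joint category layout in index order."""
    cells = []
    for s in TERTILE_LABELS:
        for m in TERTILE_LABELS:
            for d in TERTILE_LABELS:
                k = cell_index(s, m, d)
                cells.append(
                    JointExposureCategory(s, m, d, k, is_referent=(k == 1))
                )
    return sorted(cells, key=lambda c: c.cell_index)
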