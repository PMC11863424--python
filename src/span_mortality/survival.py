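"""Cox proportional-hazards fitting for joint SPAN exposures.

Two model forms are supported:

* ``joint_categorical`` — the 27-cell joint tertile model: 26 indicator
  coefficients relative to the all-low referent cell, plus covariates;
* ``continuous_additive`` — additive restricted-cubic-spline (or linear)
  terms for sleep, MVPA and DQS as independent terms, plus covariates.

Partial-likelihood maximisation is delegated to lifelines (Efron tie
handling); this module owns the design construction (spline bases, cell
dummies), hazard-ratio contrasts with Wald intervals on the log scale,
Schoenfeld-residual proportionality checks, and crude absolute risks per
10,000 person-years with exact Poisson intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats

__all__ = [
    "EXPOSURES",
    "NoEventsError",
    "SplineSpec",
    "HazardFit",
    "HRPrediction",
    "fit_joint_tertile_model",
    "fit_continuous_model",
    "predict_hr",
    "cell_hr_table",
    "check_ph",
    "absolute_risk",
    "rcs_basis",
    "default_spline_spec",
]

EXPOSURES = ("sleep", "mvpa", "dqs")

#: lifelines Newton solver options (tight gradient tolerance; hard cap on
#: iterations; non-convergence raises).
_FIT_OPTIONS = {"precision": 1e-9, "max_steps": 100}


class NoEventsError(ValueError):
    """Raised when a cohort contains no events (nothing to fit)."""


@dataclass(frozen=True)
class SplineSpec:
    """Spline specification for one exposure.

    ``kind='rcs'`` uses a restricted cubic spline with the given knots
    (Harrell truncated-power basis: linear tails, k-1 columns for k knots);
    ``kind='linear'`` uses the raw exposure as a single column.
    """

    kind: str = "rcs"
    knots: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("rcs", "linear"):
            raise ValueError(f"spline kind must be 'rcs' or 'linear', got {self.kind!r}")
        if self.kind == "rcs":
            if len(self.knots) < 3:
                raise ValueError("rcs spline needs at least 3 knots")
            if np.any(np.diff(self.knots) <= 0):
                raise ValueError("knots must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return 1 if self.kind == "linear" else len(self.knots) - 1


def rcs_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (Harrell truncated-power form).

    Returns an (n, k-1) array: the identity column plus k-2 nonlinear
    columns constrained to be linear beyond the boundary knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(knots, dtype=float)
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.maximum(x - t[j], 0) ** 3
            - np.maximum(x - t[-2], 0) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.maximum(x - t[-1], 0) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def default_spline_spec(values, percentiles=(10, 50, 90)) -> SplineSpec:
    """3-knot restricted cubic spline at the 10th/50th/90th percentiles."""
    knots = np.percentile(np.asarray(values, dtype=float), percentiles)
    if len(np.unique(knots)) < len(knots):
        raise ValueError("duplicate knots; exposure too discrete for rcs")
    return SplineSpec(kind="rcs", knots=tuple(float(v) for v in knots))


@dataclass(frozen=True)
class HRPrediction:
    """Hazard ratio between two exposure points with a 95% Wald CI."""

    hr: float
    ci_lo: float
    ci_hi: float
    target_point: dict
    reference_point: dict


@dataclass
class HazardFit:
    """A fitted Cox model: coefficients, covariance and design metadata."""

    model_form: str
    coefficients: pd.Series
    covariance: pd.DataFrame
    n: int
    n_events: int
    spline_specs: dict[str, SplineSpec] | None = None
    exposure_ranges: dict[str, tuple[float, float]] | None = None
    exposure_values: dict[str, np.ndarray] | None = None
    covariate_cols: tuple[str, ...] = ()
    log_likelihood: float = float("nan")
    cell_events: dict[int, int] | None = None
    _fitter: CoxPHFitter | None = field(default=None, repr=False)
    _design: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_coefficients(
        cls,
        coefficients: Mapping[str, float],
        exposure_ranges: Mapping[str, tuple[float, float]],
        covariance: pd.DataFrame | None = None,
        exposure_values: Mapping[str, np.ndarray] | None = None,
    ) -> "HazardFit":
        """Build a continuous fit directly from per-unit log-HRs.

        Used for synthetic hazard surfaces with known coefficients (each
        exposure enters linearly).  Zero covariance unless supplied.
        """
        names = list(coefficients)
        coefs = pd.Series({k: float(v) for k, v in coefficients.items()})
        if covariance is None:
            covariance = pd.DataFrame(
                np.zeros((len(names), len(names))), index=names, columns=names
            )
        return cls(
            model_form="continuous_additive",
            coefficients=coefs,
            covariance=covariance,
            n=0,
            n_events=0,
            spline_specs={k: SplineSpec(kind="linear") for k in coefficients},
            exposure_ranges={k: tuple(v) for k, v in exposure_ranges.items()},
            exposure_values=(
                {k: np.asarray(v, float) for k, v in exposure_values.items()}
                if exposure_values
                else None
            ),
        )

    # -- serialisation ------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "model_form": self.model_form,
            "coefficients": self.coefficients.to_dict(),
            "covariance": {
                "index": list(self.covariance.index),
                "values": self.covariance.to_numpy().tolist(),
            },
            "n": self.n,
            "n_events": self.n_events,
            "covariate_cols": list(self.covariate_cols),
            "log_likelihood": self.log_likelihood,
            "spline_specs": (
                {
                    k: {"kind": s.kind, "knots": list(s.knots)}
                    for k, s in self.spline_specs.items()
                }
                if self.spline_specs
                else None
            ),
            "exposure_ranges": (
                {k: list(v) for k, v in self.exposure_ranges.items()}
                if self.exposure_ranges
                else None
            ),
            "cell_events": self.cell_events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HazardFit":
        with open(path) as fh:
            p = json.load(fh)
        idx = p["covariance"]["index"]
        return cls(
            model_form=p["model_form"],
            coefficients=pd.Series(p["coefficients"]),
            covariance=pd.DataFrame(p["covariance"]["values"], index=idx, columns=idx),
            n=p["n"],
            n_events=p["n_events"],
            covariate_cols=tuple(p["covariate_cols"]),
            log_likelihood=p["log_likelihood"],
            spline_specs=(
                {
                    k: SplineSpec(kind=s["kind"], knots=tuple(s["knots"]))
                    for k, s in p["spline_specs"].items()
                }
                if p["spline_specs"]
                else None
            ),
            exposure_ranges=(
                {k: tuple(v) for k, v in p["exposure_ranges"].items()}
                if p["exposure_ranges"]
                else None
            ),
            cell_events=(
                {int(k): v for k, v in p["cell_events"].items()}
                if p.get("cell_events")
                else None
            ),
        )


def _run_cox(design: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    if design[event_col].sum() == 0:
        raise NoEventsError("cohort contains no events; cannot fit Cox model")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                design,
                duration_col=duration_col,
                event_col=event_col,
                fit_options=dict(_FIT_OPTIONS),
            )
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox partial-likelihood fit failed to converge: {exc}")
    return cph


def fit_joint_tertile_model(
    cohort: pd.DataFrame,
    covariate_cols: Sequence[str] = (),
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> HazardFit:
    """Fit the 27-cell joint tertile Cox model.

    Requires a ``cell_index`` column (1..27, see
    :func:`span_mortality.cohort_prep.assign_joint_categories`).  Cell 1
    (all-low) is the referent and carries no coefficient.  Cells with no
    participants are dropped with a warning; cells with participants but no
    events are fitted anyway and flagged as unstable in
    :func:`cell_hr_table`.
    """
    if "cell_index" not in cohort.columns:
        raise ValueError("cohort lacks 'cell_index'; run assign_joint_categories first")
    present = sorted(cohort["cell_index"].unique())
    empty = sorted(set(range(1, 28)) - set(present))
    if empty:
        warnings.warn(f"empty joint-exposure cells dropped from model: {empty}")
    design = pd.DataFrame(index=cohort.index)
    for c in present:
        if c == 1:
            continue
        design[f"cell_{c}"] = (cohort["cell_index"] == c).astype(float)
    for cov in covariate_cols:
        design[cov] = cohort[cov].astype(float)
    design[duration_col] = cohort[duration_col]
    design[event_col] = cohort[event_col]
    cph = _run_cox(design, duration_col, event_col)
    cell_events = (
        cohort.groupby("cell_index")[event_col].sum().astype(int).to_dict()
    )
    return HazardFit(
        model_form="joint_categorical",
        coefficients=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        n=len(cohort),
        n_events=int(cohort[event_col].sum()),
        covariate_cols=tuple(covariate_cols),
        log_likelihood=float(cph.log_likelihood_),
        cell_events=cell_events,
        _fitter=cph,
        _design=design,
    )


def _exposure_design(
    cohort: pd.DataFrame, specs: Mapping[str, SplineSpec]
) -> pd.DataFrame:
    cols = {}
    for name, spec in specs.items():
        x = cohort[name].to_numpy(dtype=float)
        if spec.kind == "linear":
            cols[name] = x
        else:
            basis = rcs_basis(x, spec.knots)
            if np.linalg.matrix_rank(basis) < basis.shape[1]:
                raise ValueError(f"singular spline basis for exposure '{name}'")
            cols[name] = basis[:, 0]
            for j in range(1, basis.shape[1]):
                cols[f"{name}_rcs{j}"] = basis[:, j]
    return pd.DataFrame(cols, index=cohort.index)


def _point_row(point: Mapping[str, float], specs: Mapping[str, SplineSpec]) -> dict:
    row = {}
    for name, spec in specs.items():
        x = float(point[name])
        if spec.kind == "linear":
            row[name] = x
        else:
            basis = rcs_basis([x], spec.knots)[0]
            row[name] = basis[0]
            for j in range(1, len(basis)):
                row[f"{name}_rcs{j}"] = basis[j]
    return row


def fit_continuous_model(
    cohort: pd.DataFrame,
    spline_specs: Mapping[str, SplineSpec] | None = None,
    covariate_cols: Sequence[str] = (),
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> HazardFit:
    """Fit the continuous additive Cox model.

    Sleep, MVPA and DQS enter as independent (additive) restricted cubic
    spline terms — 3 knots at the 10th/50th/90th percentiles by default —
    with no exposure-by-exposure interactions; covariates enter linearly.
    Exposures should already be Winsorized.
    """
    if spline_specs is None:
        spline_specs = {e: default_spline_spec(cohort[e]) for e in EXPOSURES}
    design = _exposure_design(cohort, spline_specs)
    for cov in covariate_cols:
        design[cov] = cohort[cov].astype(float)
    design[duration_col] = cohort[duration_col]
    design[event_col] = cohort[event_col]
    cph = _run_cox(design, duration_col, event_col)
    return HazardFit(
        model_form="continuous_additive",
        coefficients=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        n=len(cohort),
        n_events=int(cohort[event_col].sum()),
        spline_specs=dict(spline_specs),
        exposure_ranges={
            e: (float(cohort[e].min()), float(cohort[e].max()))
            for e in spline_specs
        },
        exposure_values={
            e: cohort[e].to_numpy(dtype=float) for e in spline_specs
        },
        covariate_cols=tuple(covariate_cols),
        log_likelihood=float(cph.log_likelihood_),
        _fitter=cph,
        _design=design,
    )


def _check_in_range(fit: HazardFit, point: Mapping[str, float]) -> None:
    for name, (lo, hi) in (fit.exposure_ranges or {}).items():
        v = float(point[name])
        if not lo <= v <= hi:
            raise ValueError(
                f"{name}={v} outside the fitted exposure range [{lo}, {hi}]"
            )


def predict_hr(
    fit: HazardFit,
    target_point: Mapping[str, float],
    reference_point: Mapping[str, float],
    allow_extrapolation: bool = False,
) -> HRPrediction:
    """Hazard ratio of ``target_point`` vs ``reference_point``.

    HR = exp(c'beta) where c is the spline-basis contrast between the two
    exposure points (covariates cancel); the 95% CI is Wald on the log
    scale using the coefficient covariance.  Points must lie inside the
    fitted exposure range unless ``allow_extrapolation``.
    """
    if fit.model_form != "continuous_additive":
        raise ValueError("predict_hr requires the continuous additive model")
    if not allow_extrapolation:
        _check_in_range(fit, target_point)
        _check_in_range(fit, reference_point)
    rt = _point_row(target_point, fit.spline_specs)
    rr = _point_row(reference_point, fit.spline_specs)
    contrast = pd.Series(0.0, index=fit.coefficients.index)
    for k in rt:
        contrast[k] = rt[k] - rr[k]
    log_hr = float(contrast @ fit.coefficients)
    var = float(contrast @ fit.covariance.to_numpy() @ contrast)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return HRPrediction(
        hr=float(np.exp(log_hr)),
        ci_lo=float(np.exp(log_hr - z * se)),
        ci_hi=float(np.exp(log_hr + z * se)),
        target_point=dict(target_point),
        reference_point=dict(reference_point),
    )


def cell_hr_table(fit: HazardFit) -> pd.DataFrame:
    """Per-cell hazard ratios for the 27-cell joint model.

    One row per cell present in the fit; the referent (cell 1) has HR
    exactly 1.  Cells with zero events are flagged ``unstable`` (their CIs
    reflect separation and should not be interpreted).
    """
    if fit.model_form != "joint_categorical":
        raise ValueError("cell_hr_table requires the joint categorical model")
    from .cohort_prep import all_cells

    z = stats.norm.ppf(0.975)
    rows = []
    for cell in all_cells():
        name = f"cell_{cell.cell_index}"
        if cell.cell_index == 1:
            hr, lo, hi, unstable = 1.0, 1.0, 1.0, False
        elif name in fit.coefficients.index:
            b = float(fit.coefficients[name])
            se = float(np.sqrt(fit.covariance.loc[name, name]))
            hr, lo, hi = np.exp(b), np.exp(b - z * se), np.exp(b + z * se)
            unstable = (
                fit.cell_events is not None
                and fit.cell_events.get(cell.cell_index, 0) == 0
            ) or se > 10
        else:
            continue  # empty cell, dropped at fit time
        rows.append(
            {
                "cell_index": cell.cell_index,
                "sleep_tertile": cell.sleep_tertile,
                "mvpa_tertile": cell.mvpa_tertile,
                "dqs_tertile": cell.dqs_tertile,
                "is_referent": cell.is_referent,
                "n_events": (
                    fit.cell_events.get(cell.cell_index, 0)
                    if fit.cell_events
                    else np.nan
                ),
                "hr": float(hr),
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "unstable": bool(unstable),
            }
        )
    return pd.DataFrame(rows)


def check_ph(
    fit: HazardFit, time_transform: str = "rank", alpha: float = 0.05
) -> pd.DataFrame:
    """Schoenfeld-residual proportional-hazards check.

    Score test of the scaled Schoenfeld residuals against a transform of
    time, per model term.  Returns a frame with per-term statistics and
    p-values plus a ``reject`` flag at the Bonferroni-adjusted ``alpha``;
    ``frame.attrs['global_ok']`` is False if any term rejects.
    """
    if fit._fitter is None or fit._design is None:
        raise ValueError("check_ph requires a live fit (not a deserialised one)")
    n_terms = len(fit.coefficients)
    if fit.n_events < n_terms:
        raise ValueError(
            f"too few events ({fit.n_events}) for {n_terms} model terms"
        )
    res = proportional_hazard_test(
        fit._fitter, fit._design, time_transform=time_transform
    )
    out = res.summary.reset_index(names=["term", "transform"] if
                                  res.summary.index.nlevels == 2 else "term")
    if "transform" not in out.columns:
        out["transform"] = time_transform
    out["reject"] = out["p"] < alpha / n_terms
    out.attrs["global_ok"] = bool(~out["reject"].any())
    return out


def absolute_risk(
    cohort: pd.DataFrame,
    group_col: str,
    duration_col: str = "followup_years",
    event_col: str = "event",
    per: float = 10_000.0,
) -> pd.DataFrame:
    """Crude event rate per ``per`` person-years by group, exact Poisson CI.

    Rate = events / person-years x ``per``.  The 95% interval uses the
    chi-square (Garwood) construction; zero events give a lower bound of 0.
    """
    rows = []
    for g, sub in cohort.groupby(group_col, observed=True):
        py = float(sub[duration_col].sum())
        if py <= 0:
            raise ValueError(f"group {g!r} has zero person-years")
        k = int(sub[event_col].sum())
        lo = stats.chi2.ppf(0.025, 2 * k) / 2 if k > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * (k + 1)) / 2
        rows.append(
            {
                group_col: g,
                "n": len(sub),
                "n_events": k,
                "person_years": py,
                "rate": k / py * per,
                "ci_lo": lo / py * per,
                "ci_hi": hi / py * per,
            }
        )
    return pd.DataFrame(rows)
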