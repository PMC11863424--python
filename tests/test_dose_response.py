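"""Dose grid, per-exposure minimal doses, combined-minimum-dose search."""

import numpy as np
import pytest

from span_mortality.dose_response import (
    FINE_STEPS,
    ReferenceAnchor,
    anchor_from_median,
    anchor_from_percentile,
    build_grid,
    combined_minimum_dose,
    dose_combinations,
    guideline_anchor,
    individual_minimal_dose,
    minimal_dose_ladder,
    percentile_axis,
)
from span_mortality.survival import EXPOSURES, HazardFit, predict_hr

BETAS = {"sleep": -0.20, "mvpa": -0.02, "dqs": -0.015}


def _uniform_surface(n=20_001):
    """Known log-linear surface over uniform exposure samples.

    Uniform marginals make quantiles linear in the percentile level, so
    log-HR is linear in equal-percentile path steps (closed-form oracle).
    """
    samples = {
        "sleep": np.linspace(4.0, 10.0, n),
        "mvpa": np.linspace(5.0, 105.0, n),
        "dqs": np.linspace(30.0, 75.0, n),
    }
    fit = HazardFit.from_coefficients(
        BETAS,
        exposure_ranges={e: (v.min(), v.max()) for e, v in samples.items()},
        exposure_values=samples,
    )
    return fit, samples


def _anchor(samples, pct=5.0):
    q = {e: float(np.percentile(v, pct)) for e, v in samples.items()}
    return ReferenceAnchor("fifth_percentile", q["sleep"], q["mvpa"], q["dqs"])


def _path_log_hr_per_pct(samples):
    """Closed-form log-HR per 1-percentile lock-step advance."""
    return sum(
        BETAS[e] * (samples[e].max() - samples[e].min()) / 100.0
        for e in EXPOSURES
    )


class TestAnchors:
    def test_percentile_and_median_anchor_values(self, prepared_cohort):
        a5 = anchor_from_percentile(prepared_cohort, 5.0)
        assert a5.kind == "fifth_percentile"
        assert a5.sleep == pytest.approx(
            np.percentile(prepared_cohort["sleep"], 5)
        )
        med = anchor_from_median(prepared_cohort)
        assert med.mvpa == pytest.approx(prepared_cohort["mvpa"].median())

    def test_guideline_defaults(self):
        g = guideline_anchor()
        assert (g.sleep, g.mvpa, g.dqs) == (7.0, 20.0, 47.5)


def test_percentile_axis_rounds_levels_to_fives():
    x = np.linspace(0, 100, 10_001)
    ax = percentile_axis(x, levels=(12, 28, 50, 71, 90))
    # levels snap to 10/30/50/70/90 before mapping to exposure values
    assert np.allclose(ax, [10, 30, 50, 70, 90], atol=0.02)


class TestGrid:
    def test_anchor_cell_is_unity(self):
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        grid = build_grid(fit, anchor)
        assert grid.hr[0, 0, 0] == pytest.approx(1.0)

    def test_matches_closed_form_elementwise(self):
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        grid = build_grid(fit, anchor)
        for i, s in enumerate(grid.sleep_axis):
            for j, m in enumerate(grid.mvpa_axis):
                for k, d in enumerate(grid.dqs_axis):
                    expected = np.exp(
                        BETAS["sleep"] * (s - anchor.sleep)
                        + BETAS["mvpa"] * (m - anchor.mvpa)
                        + BETAS["dqs"] * (d - anchor.dqs)
                    )
                    assert grid.hr[i, j, k] == pytest.approx(expected)

    def test_monotone_under_protective_truth(self):
        fit, samples = _uniform_surface()
        grid = build_grid(fit, _anchor(samples))
        assert np.all(np.diff(grid.hr, axis=0) <= 1e-12)
        assert np.all(np.diff(grid.hr, axis=1) <= 1e-12)
        assert np.all(np.diff(grid.hr, axis=2) <= 1e-12)

    def test_long_format_export(self):
        fit, samples = _uniform_surface()
        grid = build_grid(fit, _anchor(samples))
        frame = grid.to_frame()
        assert set(frame.columns) == {"sleep", "mvpa", "dqs", "hr", "ci_lo", "ci_hi"}
        assert len(frame) == grid.hr.size


class TestIndividualDose:
    def test_zero_target_zero_delta(self):
        fit, samples = _uniform_surface()
        d, p = individual_minimal_dose(fit, "mvpa", 0.0, _anchor(samples))
        assert d == 0.0
        assert p.hr == pytest.approx(1.0)

    def test_closed_form_crossing(self):
        # beta = log(0.9) per 10 units -> 10% target crosses at delta = 10
        samples = {
            "sleep": np.linspace(4, 10, 1001),
            "mvpa": np.linspace(5, 105, 1001),
            "dqs": np.linspace(30, 75, 1001),
        }
        fit = HazardFit.from_coefficients(
            {"sleep": 0.0, "mvpa": np.log(0.9) / 10.0, "dqs": 0.0},
            exposure_ranges={e: (v.min(), v.max()) for e, v in samples.items()},
            exposure_values=samples,
        )
        d, p = individual_minimal_dose(fit, "mvpa", 10.0, _anchor(samples))
        assert d == pytest.approx(10.0, abs=FINE_STEPS["mvpa"])
        assert p.hr <= 0.9

    def test_weak_effect_unreachable(self):
        fit, samples = _uniform_surface()
        weak = HazardFit.from_coefficients(
            {"sleep": 0.0, "mvpa": 0.0, "dqs": -0.001},
            exposure_ranges=fit.exposure_ranges,
            exposure_values=samples,
        )
        d, best = individual_minimal_dose(weak, "dqs", 50.0, _anchor(samples))
        assert d is None
        assert best.hr > 0.5  # best achievable falls short of the target


class TestCombinedDose:
    def test_closed_form_crossing_every_target(self):
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        step_pct = 0.1
        log_hr_per_pct = _path_log_hr_per_pct(samples)
        for target in (10, 20, 30, 40, 50, 60, 70):
            res = combined_minimum_dose(
                fit, target, anchor, step_pct=step_pct
            )
            assert res.reached
            # closed form: smallest k with k*step_pct*log_hr_per_pct <= log(1-t)
            k_exact = np.ceil(
                np.log(1 - target / 100.0) / (log_hr_per_pct * step_pct) - 1e-9
            )
            achieved_pct = (
                res.delta_mvpa_min / (np.ptp(samples["mvpa"]) / 100.0)
            )
            assert achieved_pct == pytest.approx(
                k_exact * step_pct, abs=step_pct
            )

    def test_search_consistent_with_grid_prediction(self):
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        res = combined_minimum_dose(fit, 30, anchor)
        point = {
            "sleep": anchor.sleep + res.delta_sleep_min / 60.0,
            "mvpa": anchor.mvpa + res.delta_mvpa_min,
            "dqs": anchor.dqs + res.delta_dqs_points,
        }
        direct = predict_hr(fit, point, anchor.as_dict())
        assert res.achieved.hr == pytest.approx(direct.hr, rel=1e-9)

    def test_coarse_grid_enumeration_agrees_with_path_search(self):
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        target = 30.0
        threshold = 1 - target / 100.0
        # exhaustive 20-step enumeration along each axis percentile ladder
        pcts = np.linspace(5, 100, 20)
        axes = {e: np.percentile(samples[e], pcts) for e in EXPOSURES}
        hr = np.empty((20, 20, 20))
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    hr[i, j, k] = np.exp(
                        BETAS["sleep"] * (axes["sleep"][i] - anchor.sleep)
                        + BETAS["mvpa"] * (axes["mvpa"][j] - anchor.mvpa)
                        + BETAS["dqs"] * (axes["dqs"][k] - anchor.dqs)
                    )
        diag = np.array([hr[i, i, i] for i in range(20)])
        brute_pct = pcts[np.argmax(diag <= threshold)]
        res = combined_minimum_dose(fit, target, anchor, step_pct=0.1)
        path_pct = 5.0 + res.delta_mvpa_min / (np.ptp(samples["mvpa"]) / 100.0)
        coarse_step = pcts[1] - pcts[0]
        assert abs(brute_pct - path_pct) <= coarse_step

    def test_zero_target_zero_deltas(self):
        fit, samples = _uniform_surface()
        res = combined_minimum_dose(fit, 0.0, _anchor(samples))
        assert res.delta_sleep_min == pytest.approx(0.0)
        assert res.delta_mvpa_min == pytest.approx(0.0)
        assert res.delta_dqs_points == pytest.approx(0.0)

    def test_log_linearity_doubling(self):
        # doubling the log risk-reduction target doubles the path steps
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        r1 = combined_minimum_dose(fit, 10.0, anchor, step_pct=0.01)
        r2 = combined_minimum_dose(fit, 19.0, anchor, step_pct=0.01)
        assert r2.delta_mvpa_min == pytest.approx(
            2 * r1.delta_mvpa_min, abs=0.05
        )

    def test_unreachable_target_reports_best(self):
        samples = {
            "sleep": np.linspace(4, 10, 501),
            "mvpa": np.linspace(5, 105, 501),
            "dqs": np.linspace(30, 75, 501),
        }
        weak = HazardFit.from_coefficients(
            {"sleep": -0.001, "mvpa": -0.0001, "dqs": -0.0001},
            exposure_ranges={e: (v.min(), v.max()) for e, v in samples.items()},
            exposure_values=samples,
        )
        res = combined_minimum_dose(weak, 50.0, _anchor(samples))
        assert not res.reached
        assert res.achieved.hr > 0.5


class TestLadder:
    def test_monotone_deltas_and_thresholds(self):
        fit, samples = _uniform_surface()
        anchor = _anchor(samples)
        lad = minimal_dose_ladder(fit, anchor, include_individual=False)
        assert (np.diff(lad["delta_sleep_min"]) >= 0).all()
        assert (np.diff(lad["delta_mvpa_min"]) >= 0).all()
        assert (np.diff(lad["delta_dqs_points"]) >= 0).all()
        reached = lad[lad["reached"]]
        assert (
            reached["hr"] <= 1 - reached["target_reduction_pct"] / 100 + 1e-9
        ).all()

    def test_on_fitted_model(self, cont_fit, prepared_cohort):
        anchor = anchor_from_percentile(prepared_cohort, 5.0)
        lad = minimal_dose_ladder(
            cont_fit, anchor, targets=(10, 20), include_individual=True
        )
        assert len(lad) == 2
        assert set(lad.columns) >= {
            "delta_sleep_min", "delta_mvpa_min", "delta_dqs_points",
            "hr", "ci_lo", "ci_hi",
        }


def test_combination_matrix_mode():
    fit, samples = _uniform_surface()
    anchor = _anchor(samples)
    combos = dose_combinations(fit, 30.0, anchor, tol=0.05)
    assert (np.abs(combos["hr"] - 0.7) <= 0.05).all()
    assert len(combos) > 0
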