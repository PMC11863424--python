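"""Cox model forms, HR contrasts, proportionality check, absolute risk."""

import numpy as np
import pandas as pd
import pytest

import span_mortality as sm
from span_mortality import cohort_prep, survival
from span_mortality.survival import (
    HazardFit,
    SplineSpec,
    absolute_risk,
    cell_hr_table,
    check_ph,
    fit_continuous_model,
    fit_joint_tertile_model,
    predict_hr,
    rcs_basis,
)


def test_rcs_basis_linear_tails():
    knots = (2.0, 5.0, 8.0)
    x = np.linspace(-5, 1.9, 50)
    b = rcs_basis(x, knots)
    # below the first knot the nonlinear column vanishes (linear tail)
    assert np.allclose(b[:, 1], 0.0)
    # above the last knot the basis is linear in x: second differences ~ 0
    xr = np.linspace(8.5, 20, 50)
    br = rcs_basis(xr, knots)
    assert np.allclose(np.diff(br[:, 1], 2), 0.0, atol=1e-8)


def test_spline_spec_validation():
    with pytest.raises(ValueError):
        SplineSpec(kind="rcs", knots=(1.0, 2.0))
    with pytest.raises(ValueError):
        SplineSpec(kind="rcs", knots=(1.0, 1.0, 2.0))
    with pytest.raises(ValueError):
        SplineSpec(kind="cubic")


class TestJointTertileModel:
    def test_referent_hr_is_one(self, joint_fit):
        tab = cell_hr_table(joint_fit)
        ref = tab[tab["is_referent"]]
        assert len(ref) == 1
        assert ref["hr"].iloc[0] == 1.0

    def test_26_cell_coefficients(self, joint_fit):
        cells = [c for c in joint_fit.coefficients.index if c.startswith("cell_")]
        assert len(cells) == 26

    def test_known_cell_effect_recovered(self):
        # exponential times with hazard exp(-1) x baseline in the best cell
        cfg = sm.SyntheticCohortConfig(n_participants=12_000, seed=31)
        co = sm.generate_exposures(cfg)
        cuts = {e: cohort_prep.tertile_cuts(co[e], name=e)
                for e in survival.EXPOSURES}
        co = cohort_prep.assign_joint_categories(
            co, cuts["sleep"], cuts["mvpa"], cuts["dqs"]
        )
        rng = np.random.default_rng(5)
        rate = np.where(co["cell_index"] == 27, 0.02 * np.exp(-1.0), 0.02)
        t = rng.exponential(1 / rate)
        co["followup_years"] = np.minimum(t, 8.0)
        co["event"] = (t <= 8.0).astype(int)
        fit = fit_joint_tertile_model(co)
        b = fit.coefficients["cell_27"]
        se = np.sqrt(fit.covariance.loc["cell_27", "cell_27"])
        assert abs(b - (-1.0)) < 3 * se

    def test_requires_cell_index(self, small_config):
        co = sm.generate_cohort(small_config)
        with pytest.raises(ValueError, match="cell_index"):
            fit_joint_tertile_model(co)


class TestContinuousModel:
    def test_reference_prediction_is_unity_with_zero_width(self, cont_fit):
        point = {"sleep": 7.5, "mvpa": 30.0, "dqs": 54.0}
        p = predict_hr(cont_fit, point, point)
        assert p.hr == pytest.approx(1.0)
        assert p.ci_lo == pytest.approx(1.0)
        assert p.ci_hi == pytest.approx(1.0)

    def test_closed_form_log_linear_contrast(self):
        beta = np.log(0.9)
        fit = HazardFit.from_coefficients(
            {"sleep": 0.0, "mvpa": 0.0, "dqs": beta},
            exposure_ranges={"sleep": (4, 10), "mvpa": (5, 100), "dqs": (30, 75)},
        )
        p = predict_hr(
            fit,
            {"sleep": 7, "mvpa": 30, "dqs": 52},
            {"sleep": 7, "mvpa": 30, "dqs": 50},
        )
        assert p.hr == pytest.approx(np.exp(2 * beta))  # ~0.81

    def test_fitted_curve_tracks_log_linear_truth(self):
        beta = np.log(0.85)  # per 10 DQS points
        cfg = sm.SyntheticCohortConfig(n_participants=20_000, seed=13)
        truth = sm.TrueHazardModel(beta_dqs=beta / 10.0)
        co = sm.simulate_survival(sm.generate_exposures(cfg), truth, cfg)
        fit = fit_continuous_model(co)
        lo, hi = np.percentile(co["dqs"], [5, 90])
        ref = {"sleep": 7.6, "mvpa": 31.0, "dqs": lo}
        for dqs in np.linspace(lo, hi, 5)[1:]:
            p = predict_hr(fit, ref | {"dqs": dqs}, ref)
            true_hr = np.exp(beta / 10.0 * (dqs - lo))
            assert p.ci_lo - 0.02 <= true_hr <= p.ci_hi + 0.02

    def test_nested_likelihood_ordering(self, prepared_cohort, cont_fit):
        reduced = fit_continuous_model(
            prepared_cohort,
            spline_specs={"sleep": SplineSpec(kind="linear")},
        )
        assert cont_fit.log_likelihood >= reduced.log_likelihood

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n, seed in ((2_000, 17), (20_000, 17)):
            cfg = sm.SyntheticCohortConfig(n_participants=n, seed=seed)
            co = sm.simulate_survival(
                sm.generate_exposures(cfg),
                sm.TrueHazardModel(beta_mvpa=-0.01),
                cfg,
            )
            fit = fit_continuous_model(
                co, spline_specs={"mvpa": SplineSpec(kind="linear")}
            )
            p = predict_hr(
                fit, {"mvpa": 45.0}, {"mvpa": 15.0}, allow_extrapolation=True
            )
            widths.append(np.log(p.ci_hi) - np.log(p.ci_lo))
        assert widths[1] < widths[0] / 2  # SE ~ 1/sqrt(information)

    def test_extrapolation_guard(self, cont_fit):
        lo = cont_fit.exposure_ranges["sleep"][0]
        point = {"sleep": lo - 1.0, "mvpa": 30.0, "dqs": 54.0}
        ref = {"sleep": 7.5, "mvpa": 30.0, "dqs": 54.0}
        with pytest.raises(ValueError, match="outside"):
            predict_hr(cont_fit, point, ref)
        predict_hr(cont_fit, point, ref, allow_extrapolation=True)

    def test_covariate_affine_recoding_leaves_hr_invariant(self, prepared_cohort):
        point = {"sleep": 8.0, "mvpa": 40.0, "dqs": 60.0}
        ref = {"sleep": 7.0, "mvpa": 20.0, "dqs": 50.0}
        a = fit_continuous_model(prepared_cohort, covariate_cols=("age",))
        recoded = prepared_cohort.copy()
        recoded["age"] = (recoded["age"] - 60.0) / 10.0
        b = fit_continuous_model(recoded, covariate_cols=("age",))
        pa = predict_hr(a, point, ref)
        pb = predict_hr(b, point, ref)
        assert pa.hr == pytest.approx(pb.hr, rel=1e-6)


class TestCheckPH:
    def test_proportional_truth_rarely_rejected(self):
        rejections = 0
        for seed in range(10):
            cfg = sm.SyntheticCohortConfig(n_participants=3_000, seed=100 + seed)
            co = sm.simulate_survival(
                sm.generate_exposures(cfg),
                sm.TrueHazardModel(beta_mvpa=-0.01),
                cfg,
            )
            fit = fit_continuous_model(
                co, spline_specs={"mvpa": SplineSpec(kind="linear")}
            )
            res = check_ph(fit)
            rejections += int(not res.attrs["global_ok"])
        assert rejections <= 3

    def test_time_varying_effect_detected(self):
        # effect reverses sign at t=4: grossly non-proportional
        rng = np.random.default_rng(2)
        n = 5_000
        x = rng.binomial(1, 0.5, n).astype(float)
        # piecewise-exponential: rate differs before/after the switch
        r_early = np.where(x == 1, 0.30, 0.10)
        r_late = np.where(x == 1, 0.02, 0.10)
        t1 = rng.exponential(1 / r_early)
        t2 = 4.0 + rng.exponential(1 / r_late)
        t = np.where(t1 < 4.0, t1, t2)
        event = (t < 8.0).astype(int)
        co = pd.DataFrame(
            {"mvpa": x, "followup_years": np.minimum(t, 8.0), "event": event}
        )
        fit = fit_continuous_model(
            co, spline_specs={"mvpa": SplineSpec(kind="linear")}
        )
        res = check_ph(fit)
        assert not res.attrs["global_ok"]

    def test_too_few_events_rejected(self, cont_fit):
        import dataclasses

        starved = dataclasses.replace(cont_fit, n_events=2)
        with pytest.raises(ValueError, match="too few events"):
            check_ph(starved)


class TestAbsoluteRisk:
    def test_hand_arithmetic(self):
        co = pd.DataFrame(
            {
                "g": ["a"] * 10 + ["b"] * 5 + ["c"] * 4,
                "followup_years": [100.0] * 10 + [40.0] * 5 + [25.0] * 4,
                "event": [1, 1] + [0] * 8 + [1] + [0] * 4 + [0] * 4,
            }
        )
        tab = absolute_risk(co, "g").set_index("g")
        assert tab.loc["a", "rate"] == pytest.approx(20.0)  # 2 / 1000 PY
        assert tab.loc["b", "rate"] == pytest.approx(50.0)  # 1 / 200 PY
        assert tab.loc["c", "rate"] == 0.0
        assert tab.loc["c", "ci_lo"] == 0.0
        assert (tab["ci_lo"] <= tab["rate"]).all()
        assert (tab["rate"] <= tab["ci_hi"]).all()

    def test_events_and_person_years_conserved(self, prepared_cohort):
        tab = absolute_risk(prepared_cohort, "cell_index")
        assert tab["n_events"].sum() == prepared_cohort["event"].sum()
        assert tab["person_years"].sum() == pytest.approx(
            prepared_cohort["followup_years"].sum()
        )

    def test_zero_person_years_rejected(self):
        co = pd.DataFrame({"g": ["a"], "followup_years": [0.0], "event": [0]})
        with pytest.raises(ValueError, match="person-years"):
            absolute_risk(co, "g")


def test_fit_json_round_trip(tmp_path, cont_fit):
    path = tmp_path / "fit.json"
    cont_fit.to_json(path)
    back = HazardFit.from_json(path)
    pd.testing.assert_series_equal(
        back.coefficients, cont_fit.coefficients, check_names=False
    )
    assert back.spline_specs == cont_fit.spline_specs
    assert back.n_events == cont_fit.n_events
    p0 = predict_hr(cont_fit, {"sleep": 8, "mvpa": 40, "dqs": 60},
                    {"sleep": 7, "mvpa": 20, "dqs": 50})
    p1 = predict_hr(back, {"sleep": 8, "mvpa": 40, "dqs": 60},
                    {"sleep": 7, "mvpa": 20, "dqs": 50})
    assert p1.hr == pytest.approx(p0.hr)
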