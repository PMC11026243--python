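import numpy as np
import pandas as pd
import pytest

from ccweight import (Regimen, SimConfig, build_clone_panel, fit_outcome_model,
                      incidence_rate, person_time_summary, simulate_cohort,
                      summary_hr, survival_curves)
from ccweight.errors import InputError
from ccweight.estimation import OutcomeFit, risk_rows

from conftest import make_history


class StubResult:
    def __init__(self, params, bse=None, hazard=None):
        self.params = pd.Series(params)
        self.bse = pd.Series(bse or {})
        self._hazard = hazard

    def predict(self, X):
        return np.full(len(X), self._hazard)


def stub_fit(params, bse, labels, hazard=None):
    return OutcomeFit(outcome="stroke",
                      result=StubResult(params, bse, hazard=hazard),
                      regimen_labels=labels,
                      design_columns=["const"] + [f"regimen_{l}" for l in labels]
                                     + ["month", "month_sq"],
                      time="quadratic", zero_event_arms=[])


class TestIncidenceRate:
    @pytest.mark.parametrize("events,py,expected", [
        (188, 4980, 37.75),
        (40, 5084, 7.87),
        (56, 9644, 5.81),
        (202, 16589, 12.18),
        (127, 16629, 7.64),
        (358, 20898, 17.13),
        (0, 100, 0.00),
    ])
    def test_rates(self, events, py, expected):
        assert incidence_rate(events, py) == expected

    def test_rounding_half_up(self):
        assert incidence_rate(125, 1000000) == 0.13

    @pytest.mark.parametrize("events,py", [(1, 0), (1, -5), (-1, 10)])
    def test_invalid_inputs(self, events, py):
        with pytest.raises(InputError):
            incidence_rate(events, py)


class TestPersonTime:
    def test_full_follow_up_no_event(self):
        panel = make_history(0, [2] * 12)
        clones = build_clone_panel(panel, [Regimen("never")])
        clones["truncated_weight"] = 1.0
        out = person_time_summary(clones, "stroke").iloc[0]
        assert out["person_years"] == 1.0
        assert out["events"] == 0

    def test_censored_at_month_six(self):
        panel = make_history(0, [2] * 12, init_month=6)
        clones = build_clone_panel(panel, [Regimen("never")])
        out = person_time_summary(clones, "stroke").iloc[0]
        assert out["person_years"] == 0.5

    def test_event_truncates_follow_up(self):
        panel = make_history(0, [2] * 12, stroke_month=4)
        clones = build_clone_panel(panel, [Regimen("never")])
        out = person_time_summary(clones, "stroke").iloc[0]
        assert out["events"] == 1
        assert out["person_years"] == pytest.approx(5 / 12)

    def test_row_count_oracle(self):
        cfg = SimConfig(n_patients=50, seed=77)
        panel = simulate_cohort(cfg)
        regimens = [Regimen("threshold", 2), Regimen("never")]
        clones = build_clone_panel(panel, regimens)
        table = person_time_summary(clones, "bleed").set_index("regimen")
        for lab in table.index:
            months = 0
            events = 0
            arm = clones[clones["regimen"] == lab]
            for _, grp in arm.groupby("patient_id"):
                seen = False
                for _, row in grp.sort_values("month").iterrows():
                    if row["artificially_censored"] or seen:
                        continue
                    months += 1
                    if row["event_bleed"]:
                        events += 1
                        seen = True
            assert table.loc[lab, "events"] == events
            assert table.loc[lab, "person_years"] == pytest.approx(months / 12)


class TestSummaryHR:
    def test_null_coefficient(self):
        table = summary_hr(stub_fit({"regimen_a": 0.0}, {"regimen_a": 0.1}, ["a"]))
        row = table.iloc[0]
        assert row["hr"] == pytest.approx(1.00, abs=5e-3)
        assert row["ci_lower"] == pytest.approx(0.82, abs=5e-3)
        assert row["ci_upper"] == pytest.approx(1.22, abs=5e-3)

    def test_protective_coefficient(self):
        table = summary_hr(stub_fit({"regimen_a": -0.446}, {"regimen_a": 0.05}, ["a"]))
        row = table.iloc[0]
        assert row["hr"] == pytest.approx(0.64, abs=5e-3)
        assert row["ci_lower"] == pytest.approx(0.58, abs=5e-3)
        assert row["ci_upper"] == pytest.approx(0.71, abs=5e-3)

    def test_ci_brackets_point(self):
        table = summary_hr(stub_fit({"regimen_a": 0.3}, {"regimen_a": 0.2}, ["a"]))
        row = table.iloc[0]
        assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]
        assert row["hr"] > 0


class TestSurvivalCurves:
    def test_constant_hazard_closed_form(self):
        panel = make_history(0, [2] * 12)
        clones = build_clone_panel(panel, [Regimen("never")])
        clones["truncated_weight"] = 1.0
        fit = OutcomeFit(outcome="stroke",
                         result=StubResult({}, hazard=0.01),
                         regimen_labels=[], design_columns=["const", "month", "month_sq"],
                         time="quadratic", zero_event_arms=[])
        curves = survival_curves(fit, clones)
        s12 = curves.loc[curves["month"] == 12, "survival"].iloc[0]
        assert s12 == pytest.approx(0.99 ** 12, abs=1e-12)
        assert curves.loc[curves["month"] == 0, "survival"].iloc[0] == 1.0

    def test_zero_hazard_flat_curve(self):
        panel = make_history(0, [2] * 12)
        clones = build_clone_panel(panel, [Regimen("never")])
        clones["truncated_weight"] = 1.0
        fit = OutcomeFit(outcome="stroke", result=StubResult({}, hazard=0.0),
                         regimen_labels=[], design_columns=["const"],
                         time="quadratic", zero_event_arms=[])
        curves = survival_curves(fit, clones)
        assert (curves["survival"] == 1.0).all()

    def test_curves_nonincreasing_start_at_one(self, medium_panel):
        from ccweight import (apply_eligibility, default_regimens,
                              fit_weight_models, compute_cumulative_weights,
                              truncate_weights)
        eligible, _ = apply_eligibility(medium_panel)
        regimens = default_regimens()
        clones = build_clone_panel(eligible, regimens)
        model = fit_weight_models(eligible)
        clones = truncate_weights(
            compute_cumulative_weights(clones, model, regimens), 99)
        fit = fit_outcome_model(clones, "stroke")
        curves = survival_curves(fit, clones)
        for _, grp in curves.groupby("regimen"):
            s = grp.sort_values("month")["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()

    def test_small_weighted_panel_brute_force(self):
        # 3 clones, hand-rolled weighted product over months
        frames = []
        rng = np.random.default_rng(8)
        for pid in range(3):
            panel = make_history(pid, [2] * 5,
                                 stroke_month=3 if pid == 0 else None)
            c = build_clone_panel(panel, [Regimen("never")])
            frames.append(c)
        clones = pd.concat(frames, ignore_index=True)
        clones["truncated_weight"] = rng.uniform(1, 3, len(clones))
        fit = fit_outcome_model(clones, "stroke")
        curves = survival_curves(fit, clones)
        rows = risk_rows(clones, "stroke")
        from ccweight.estimation import _outcome_design
        X = _outcome_design(rows, fit.regimen_labels, fit.time,
                            columns=fit.design_columns)
        h = np.asarray(fit.result.predict(X))
        expected = [1.0]
        for m in range(5):
            mask = rows["month"] == m
            hbar = np.average(h[mask.to_numpy()],
                              weights=rows.loc[mask, "truncated_weight"])
            expected.append(expected[-1] * (1 - hbar))
        got = curves.sort_values("month")["survival"].to_numpy()
        assert np.allclose(got, expected, atol=1e-12)


class TestOutcomeModel:
    def _manual_clones(self, events_a, events_b, n=40, months=6):
        recs = []
        for arm, events in (("a", events_a), ("never", events_b)):
            for pid in range(n):
                for m in range(months):
                    recs.append({
                        "patient_id": pid, "regimen": arm, "month": m,
                        "event_stroke": (pid, m) in events,
                        "artificially_censored": False,
                        "truncated_weight": 1.0,
                    })
        return pd.DataFrame(recs)

    def test_symmetric_arms_zero_coefficient(self):
        events = {(0, 2), (3, 4), (7, 1)}
        clones = self._manual_clones(events, events)
        fit = fit_outcome_model(clones, "stroke")
        assert abs(fit.result.params["regimen_a"]) < 1e-6

    def test_zero_event_arm_flagged(self):
        clones = self._manual_clones(set(), {(0, 2), (3, 4)})
        fit = fit_outcome_model(clones, "stroke")
        assert "a" in fit.zero_event_arms
        table = summary_hr(fit)
        assert table.loc[table["regimen"] == "a", "zero_events"].iloc[0]

    def test_weight_scale_invariance(self, medium_panel):
        from ccweight import (apply_eligibility, default_regimens,
                              fit_weight_models, compute_cumulative_weights,
                              truncate_weights)
        eligible, _ = apply_eligibility(medium_panel)
        regimens = [Regimen("threshold", 4), Regimen("never")]
        clones = build_clone_panel(eligible, regimens)
        model = fit_weight_models(eligible)
        clones = truncate_weights(
            compute_cumulative_weights(clones, model, regimens), 99)
        fit1 = fit_outcome_model(clones, "stroke")
        scaled = clones.assign(truncated_weight=clones["truncated_weight"] * 7.5)
        fit2 = fit_outcome_model(scaled, "stroke")
        assert np.allclose(fit1.result.params, fit2.result.params, atol=1e-8)

    def test_km_equivalence_unweighted_single_arm(self):
        # all weights 1, one arm, month indicators: the standardized curve
        # equals the discrete product-limit estimator
        cfg = SimConfig(n_patients=400, seed=19, init_intercept=-50.0,
                        hazard_stroke=0.03, hazard_death=0.01,
                        hazard_dropout=0.01)
        panel = simulate_cohort(cfg)
        clones = build_clone_panel(panel, [Regimen("never")])
        fit = fit_outcome_model(clones, "stroke", weight_col=None,
                                time="indicators")
        curves = survival_curves(fit, clones, weight_col=None)
        rows = risk_rows(clones, "stroke")
        km = [1.0]
        for m in range(int(rows["month"].max()) + 1):
            sub = rows[rows["month"] == m]
            km.append(km[-1] * (1 - sub["event_stroke"].mean()))
        got = curves.sort_values("month")["survival"].to_numpy()
        assert np.allclose(got, km, atol=1e-4)
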