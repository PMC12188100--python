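import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit

import t2dsim as t
from t2dsim.errors import ConfigurationError, StateError
from t2dsim.risk_models import (
    EquationSpec, LookupTable, ngt_background_mortality, patient_context,
)


def eq(form, coefficients, **kw):
    e = EquationSpec(name="test", form=form, coefficients=coefficients, **kw)
    e.validate()
    return e


class TestHazardForms:
    def test_zero_hazard_gives_zero_probability(self, toy_patient):
        e = eq("exponential_hazard", {"intercept": -760.0})
        assert e.probability(patient_context(toy_patient()))[0] == 0.0

    def test_constant_exponential_hazard_closed_form(self, toy_patient):
        e = eq("exponential_hazard", {"intercept": math.log(0.10)})
        p = e.probability(patient_context(toy_patient()))[0]
        assert p == pytest.approx(1 - math.exp(-0.10), abs=1e-12)

    def test_probability_matches_published_style_hand_evaluation(
            self, toy_patient):
        # independent spreadsheet-style evaluation of a Weibull equation on
        # a worked covariate profile
        e = eq("weibull_hazard",
               {"intercept": -5.0, "age": 0.06, "female": -0.5,
                "hba1c": 0.15},
               shape=1.4, time_scale="duration",
               transforms={"age": {"center": 60}, "hba1c": {"center": 7}})
        patient = toy_patient(hba1c=8.3, age=66.0, female=True, duration=4)
        lp = -5.0 + 0.06 * (66 - 60) - 0.5 * 1 + 0.15 * (8.3 - 7.0)
        H = math.exp(lp) * (5 ** 1.4 - 4 ** 1.4)
        expected = 1 - math.exp(-H)
        got = t.annual_event_probability(
            patient, "CHF", _single_event_table(e))
        assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("form,shape,scale", [
        ("weibull_hazard", 1.7, "duration"),
        ("weibull_hazard", 0.8, "duration"),
        ("gompertz_hazard", 0.09, "age"),
    ])
    def test_hazard_integration_matches_quadrature(self, form, shape, scale,
                                                   toy_patient):
        rng = np.random.default_rng(42)
        for _ in range(35):
            lam = float(rng.uniform(-8, -2))
            e = eq(form, {"intercept": lam}, shape=shape, time_scale=scale)
            dur = int(rng.integers(0, 15))
            age = float(rng.uniform(40, 80))
            ctx = patient_context(toy_patient(age=age, duration=dur))
            t0 = dur if scale == "duration" else age
            if form == "weibull_hazard":
                def hazard(s):
                    return math.exp(lam) * shape * s ** (shape - 1)
            else:
                def hazard(s):
                    return math.exp(lam) * math.exp(shape * s)
            H, _ = integrate.quad(hazard, t0, t0 + 1, epsabs=1e-13,
                                  epsrel=1e-13)
            p_expected = 1 - math.exp(-H)
            p = e.probability(ctx)[0]
            assert p == pytest.approx(p_expected, rel=1e-8, abs=1e-12)

    def test_probabilities_within_unit_interval_randomized(self, table,
                                                           toy_patient):
        rng = np.random.default_rng(7)
        names = list(table.event_equations)
        for _ in range(300):
            patient = toy_patient(
                hba1c=float(rng.uniform(4, 15)),
                age=float(rng.uniform(25, 95)),
                duration=int(rng.integers(0, 30)),
                sbp=float(rng.uniform(80, 220)),
                bmi=float(rng.uniform(15, 60)),
                egfr=float(rng.uniform(5, 150)),
                state=t.T2DM,
            )
            key = names[int(rng.integers(len(names)))]
            p = table.event_equations[key].probability(
                patient_context(patient))[0]
            assert 0.0 <= p <= 1.0


def _single_event_table(e):
    """Minimal stand-in exposing one equation under every T2DM chronic key."""

    class Stub:
        event_equations = {"t2dm_chf": e}

        @staticmethod
        def event_equation_key(event, state, prior=0):
            return "t2dm_chf"

    return Stub()


class TestPreT2dmLayer:
    def test_state_guard(self, toy_patient, table):
        with pytest.raises(StateError):
            t.pre_t2dm_event_probability(
                toy_patient(hba1c=8.0), "MI", table)

    def test_monotone_in_positive_coefficient(self, toy_patient, table):
        lo = toy_patient(hba1c=6.0, sbp=120.0)
        hi = toy_patient(hba1c=6.0, sbp=160.0)
        assert (t.pre_t2dm_event_probability(hi, "STROKE", table)
                > t.pre_t2dm_event_probability(lo, "STROKE", table))

    def test_intercept_only_at_centering_values(self, toy_patient):
        e = eq("exponential_hazard",
               {"intercept": math.log(0.02), "sbp": 0.02, "age": 0.05},
               transforms={"sbp": {"center": 130}, "age": {"center": 55}})
        p = e.probability(patient_context(toy_patient(age=55.0, sbp=130.0)))
        assert p[0] == pytest.approx(1 - math.exp(-0.02), abs=1e-12)


class TestJump:
    def test_jump_branch_exact(self, toy_patient, table):
        patient = toy_patient(hba1c=6.2)
        new, jumped = t.apply_hba1c_jump(patient, 0.05, table)
        assert jumped is True
        assert new == pytest.approx(6.74, abs=1e-12)

    def test_no_jump_uses_progression_equation(self, toy_patient, table):
        patient = toy_patient(hba1c=6.2)
        new, jumped = t.apply_hba1c_jump(patient, 0.50, table)
        assert jumped is False
        expected = table.risk_factor_equation("hba1c", t.NGT_PRE).update(
            patient_context(patient))[0]
        assert new == pytest.approx(expected, abs=1e-12)

    def test_outside_band_rejected(self, toy_patient, table):
        with pytest.raises(StateError):
            t.apply_hba1c_jump(toy_patient(hba1c=5.5), 0.05, table)


class TestRiskFactorUpdates:
    def test_identity_dynamics(self, toy_patient, table):
        d = table.to_dict()
        for key in list(d["risk_factor_equations"]):
            factor = key.split("@")[0]
            d["risk_factor_equations"][key] = {
                "form": "autoregressive_update",
                "coefficients": {"intercept": 0.0, factor: 1.0},
            }
        ident = type(table).from_dict(d)
        patient = toy_patient(hba1c=7.3)
        out = t.update_risk_factors(patient, ident)
        for f in ("hba1c", "bmi", "sbp", "ldl", "hdl", "egfr", "haem",
                  "wbc", "heart_rate"):
            assert getattr(out, f) == getattr(patient.risk_factors, f)

    def test_linear_update_hand_computed(self, toy_patient):
        e = eq("linear_update",
               {"intercept": 1.5, "bmi": 0.9, "hba1c": 0.2})
        ctx = patient_context(toy_patient(hba1c=7.0))
        assert e.update(ctx)[0] == pytest.approx(
            1.5 + 0.9 * 30.0 + 0.2 * 7.0, abs=1e-12)

    def test_monotone_in_signed_dependency(self, toy_patient, table):
        lo = t.update_risk_factors(toy_patient(hba1c=7.0, bmi=25.0), table)
        hi = t.update_risk_factors(toy_patient(hba1c=7.0, bmi=35.0), table)
        assert hi.sbp >= lo.sbp     # BMI enters the SBP update positively

    def test_truncation_to_bounds(self, toy_patient, table):
        out = t.update_risk_factors(toy_patient(hba1c=7.0, egfr=2.5), table)
        lo, hi = table.bounds["egfr"]
        assert lo <= out.egfr <= hi


class TestLvh:
    def test_extreme_negative_linear_predictor(self, toy_patient, table):
        d = table.to_dict()
        d["lvh_equation"]["coefficients"]["intercept"] = -745.0
        tt = type(table).from_dict(d)
        assert t.predict_lvh(toy_patient(), tt, u=0.9999) is False

    def test_midpoint_probability(self, toy_patient, table):
        d = table.to_dict()
        d["lvh_equation"] = {"form": "logistic",
                             "coefficients": {"intercept": 0.0}}
        tt = type(table).from_dict(d)
        assert t.predict_lvh(toy_patient(), tt, u=0.499) is True
        assert t.predict_lvh(toy_patient(), tt, u=0.501) is False

    def test_hand_computed_inverse_logit(self, toy_patient, table):
        d = table.to_dict()
        d["lvh_equation"] = {
            "form": "logistic",
            "coefficients": {"intercept": -2.0, "bmi": 0.05},
            "transforms": {"bmi": {"center": 30}},
        }
        d["lvh_mode"] = "threshold"
        tt = type(table).from_dict(d)
        p = tt.lvh_equation.probability(
            patient_context(toy_patient(bmi=36.0)))[0]
        assert p == pytest.approx(expit(-2.0 + 0.05 * 6.0), abs=1e-12)


class TestMortality:
    def test_selector_total_and_exclusive(self):
        keys = {t.select_mortality_equation(h, e)
                for h in (False, True) for e in (False, True)}
        assert keys == {"mort_nohist_noevent", "mort_nohist_event",
                        "mort_hist_noevent", "mort_hist_event"}

    @pytest.mark.parametrize("hist,new,key", [
        (False, False, "mort_nohist_noevent"),
        (False, True, "mort_nohist_event"),
        (True, False, "mort_hist_noevent"),
        (True, True, "mort_hist_event"),
    ])
    def test_selector_mapping(self, hist, new, key):
        assert t.select_mortality_equation(hist, new) == key

    def test_t2dm_selection_reflected_in_probability(self, toy_patient,
                                                     table):
        from scipy.special import logit
        probs = {"mort_nohist_noevent": 0.01, "mort_nohist_event": 0.2,
                 "mort_hist_noevent": 0.05, "mort_hist_event": 0.4}
        d = table.to_dict()
        for key, p in probs.items():
            d["mortality_equations"][key] = {
                "form": "logistic",
                "coefficients": {"intercept": float(logit(p))},
            }
        tt = type(table).from_dict(d)
        patient = toy_patient(hba1c=8.0)
        for hist in (False, True):
            for new in (False, True):
                key = t.select_mortality_equation(hist, new)
                got = t.t2dm_mortality_probability(patient, new, hist, tt)
                assert got == pytest.approx(probs[key], abs=1e-12)


class TestNgtMortality:
    def test_background_adjustment_closed_form(self, toy_patient, table):
        d = table.to_dict()
        q, c = 0.02, 0.005
        ngt = d["ngt_mortality"]
        ngt["background"] = {"age_bands": [0], "male": [q], "female": [q]}
        ngt["cause_removal"] = {"age_bands": [0], "male": [c], "female": [c]}
        tt = type(table).from_dict(d)
        expected = 1 - math.exp(-(-math.log(1 - q) - c))
        got = t.pre_t2dm_mortality_probability(
            toy_patient(hba1c=6.0), set(), tt)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_null_adjustment(self, toy_patient, table):
        d = table.to_dict()
        ngt = d["ngt_mortality"]
        ngt["background"] = {"age_bands": [0], "male": [0.03],
                             "female": [0.03]}
        ngt["cause_removal"] = {"age_bands": [0], "male": [0.0],
                                "female": [0.0]}
        tt = type(table).from_dict(d)
        assert t.pre_t2dm_mortality_probability(
            toy_patient(hba1c=6.0), set(), tt) == pytest.approx(0.03)

    def test_event_year_lookup(self, toy_patient, table):
        d = table.to_dict()
        d["ngt_mortality"]["case_fatality"]["STROKE"] = {
            "age_bands": [0], "male": [0.12], "female": [0.12]}
        tt = type(table).from_dict(d)
        assert t.pre_t2dm_mortality_probability(
            toy_patient(hba1c=6.0), {"STROKE"}, tt) == 0.12

    def test_multiple_events_take_maximum(self, toy_patient, table):
        d = table.to_dict()
        cf = d["ngt_mortality"]["case_fatality"]
        cf["STROKE"] = {"age_bands": [0], "male": [0.12], "female": [0.12]}
        cf["MI"] = {"age_bands": [0], "male": [0.20], "female": [0.20]}
        tt = type(table).from_dict(d)
        assert t.pre_t2dm_mortality_probability(
            toy_patient(hba1c=6.0), {"STROKE", "MI"}, tt) == 0.20

    def test_state_guard(self, toy_patient, table):
        with pytest.raises(StateError):
            t.pre_t2dm_mortality_probability(toy_patient(hba1c=9.0), set(),
                                             table)
        with pytest.raises(StateError):
            t.t2dm_mortality_probability(toy_patient(hba1c=6.0), False,
                                         False, table)


class TestConfigurationErrors:
    def test_unknown_form(self):
        with pytest.raises(ConfigurationError, match="form"):
            EquationSpec("x", "sinusoid", {"intercept": 0}).validate()

    def test_missing_intercept(self):
        with pytest.raises(ConfigurationError, match="intercept"):
            EquationSpec("x", "logistic", {"age": 0.1}).validate()

    def test_missing_predictor_named_in_error(self, toy_patient):
        e = eq("logistic", {"intercept": 0.0, "serum_unobtainium": 1.0})
        with pytest.raises(ConfigurationError, match="serum_unobtainium"):
            e.probability(patient_context(toy_patient()))

    def test_lookup_table_validation(self):
        with pytest.raises(ConfigurationError, match="ascending"):
            LookupTable(np.array([50.0, 40.0]), np.array([0.1, 0.2]),
                        np.array([0.1, 0.2])).validate("x")

    def test_jump_parameter_invariants(self, table):
        d = table.to_dict()
        d["transition"]["p_jump"] = 1.4
        with pytest.raises(ConfigurationError, match="p_jump"):
            type(table).from_dict(d)
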