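import numpy as np
import pytest

import t2dsim as t


@pytest.fixture(scope="session")
def cfg():
    return t.load_config()


@pytest.fixture(scope="session")
def table(cfg):
    return cfg.coefficients


@pytest.fixture()
def toy_patient():
    """Factory for a fully specified single patient."""

    def make(hba1c=7.0, state=None, age=60.0, female=False, duration=0,
             history=None, **rf_overrides):
        rf = dict(hba1c=hba1c, bmi=30.0, sbp=135.0, ldl=3.0, hdl=1.2,
                  egfr=80.0, haem=14.0, wbc=7.0, heart_rate=72.0)
        rf.update(rf_overrides)
        vec = t.RiskFactorVector(**rf)
        if state is None:
            state = t.classify_state(hba1c)
        return t.PatientState(
            patient_id=0, age=age, female=female, risk_factors=vec,
            state=state, years_since_t2dm=duration, history=history,
        )

    return make


@pytest.fixture(scope="session")
def toy_cohort(cfg):
    cohort, _ = t.make_fixture_cohort("toy", 5, 1, cfg)
    return cohort


def constant_prob_table(base_table, p_event=0.0, p_mort=0.0,
                        p_jump=0.129, **event_probs):
    """Clone the default table with every event/mortality probability forced
    to a constant (via logistic intercepts), keeping progression equations.

    ``event_probs`` overrides individual equation keys, e.g.
    ``t2dm_mi1=1.0``.
    """
    from scipy.special import logit

    def intercept_for(p):
        if p <= 0.0:
            return -745.0
        if p >= 1.0:
            return 745.0
        return float(logit(p))

    d = base_table.to_dict()
    for key in d["event_equations"]:
        p = event_probs.get(key, p_event)
        d["event_equations"][key] = {
            "form": "logistic",
            "coefficients": {"intercept": intercept_for(p)},
        }
    for key in d["mortality_equations"]:
        p = event_probs.get(key, p_mort)
        d["mortality_equations"][key] = {
            "form": "logistic",
            "coefficients": {"intercept": intercept_for(p)},
        }
    pm = min(max(p_mort, 0.0), 1.0)
    ngt = d["ngt_mortality"]
    for block in (ngt["background"],) + tuple(ngt["case_fatality"].values()):
        block["male"] = [pm] * len(block["male"])
        block["female"] = [pm] * len(block["female"])
    ngt["cause_removal"]["male"] = [0.0] * len(ngt["cause_removal"]["male"])
    ngt["cause_removal"]["female"] = [0.0] * len(ngt["cause_removal"]["female"])
    d["transition"]["p_jump"] = p_jump
    from t2dsim.risk_models import CoefficientTable
    return CoefficientTable.from_dict(d)
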