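"""Two-level annual simulation cycle.

Each simulated year proceeds as the model structure prescribes:

1. the patient's glycaemic state is determined from current HbA1c (diabetes
   is absorbing: once classified T2DM a patient never reverts);
2. the comorbidity probabilities applicable in that state are evaluated in a
   uniformly random order, one independent uniform per candidate event, with
   the event history updated immediately so that later events in the same
   year condition on earlier ones; chronic comorbidities are skipped once
   present and acute events are skipped at their occurrence caps (MI and
   stroke once before diabetes onset; MI, stroke and amputation up to twice
   after);
3. a single mortality evaluation follows, using the state-appropriate
   mortality model (one of four mutually exclusive equations after onset;
   event-table or cause-deleted background mortality before onset);
4. survivors receive end-of-year risk-factor updates, including the
   pre-diabetes HbA1c jump mechanism, which *replaces* the HbA1c progression
   equation in jump years; the updated HbA1c determines next year's state.

The implementation is vectorised across the cohort; per-patient operations
are thin wrappers over the same code path, so a cohort of one reproduces a
patient simulated alone.  All randomness is addressed through keyed
counter-based substreams (see :mod:`t2dsim.streams`): results are
independent of patient order and execution interleaving, and two arms
sharing a master seed share patient-level randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import streams
from .cohort import (
    CONTINUOUS_FIELDS, NGT_PRE, T2DM, T2DM_THRESHOLD, Cohort, PatientState,
    RiskFactorVector, in_pre_t2dm_band,
)
from .errors import StateError
from .risk_models import (
    ACUTE_EVENTS, CHRONIC_EVENTS, CoefficientTable, NGT_EVENTS, T2DM_EVENTS,
    ngt_background_mortality, select_mortality_equation,
)

#: canonical event order used for array layout and stream slots
EVENT_ORDER = T2DM_EVENTS
_EIDX = {ev: i for i, ev in enumerate(EVENT_ORDER)}
_NGT_SET = frozenset(NGT_EVENTS)

# substream purpose codes (first counter)
_P_PERM, _P_EVENT, _P_MORT, _P_JUMP, _P_BIN, _P_LVH = 1, 2, 3, 4, 5, 6
_BINARY_PROG = ("albuminuria", "pvd", "af")
_UPDATED_CONTINUOUS = tuple(f for f in CONTINUOUS_FIELDS if f != "age")


# --------------------------------------------------------------------------
# per-patient record types


@dataclass
class EventHistory:
    """Comorbidity history of one patient."""

    chronic_flags: dict = field(default_factory=lambda: {
        ev: False for ev in CHRONIC_EVENTS + ("ULCER",)
    })
    acute_counts: dict = field(default_factory=lambda: {
        ev: 0 for ev in ACUTE_EVENTS
    })
    pre_t2dm_acute_used: dict = field(default_factory=lambda: {
        "MI": False, "STROKE": False
    })
    current_year_events: set = field(default_factory=set)

    def ever(self, event: str) -> bool:
        if event in self.chronic_flags:
            return self.chronic_flags[event]
        used = self.pre_t2dm_acute_used.get(event, False)
        return used or self.acute_counts.get(event, 0) > 0

    def any_history(self) -> bool:
        return (any(self.chronic_flags.values())
                or any(v > 0 for v in self.acute_counts.values())
                or any(self.pre_t2dm_acute_used.values()))


@dataclass
class AnnualRecord:
    """One patient-year of simulation output."""

    year_index: int
    state_at_start: str
    events: set
    died: bool
    risk_factors_end: RiskFactorVector
    undiscounted_cost: float = 0.0
    undiscounted_qaly: float = 0.0
    age_at_start: float = float("nan")


@dataclass
class Trajectory:
    """The full simulated record stream of one patient."""

    patient_id: int
    records: list
    death_year: int | None = None
    female: bool = False
    baseline_age: float = float("nan")


class CohortResult:
    """Array-backed simulation output for a whole cohort.

    Shapes: ``events`` is (horizon, n, n_event_types); ``died``,
    ``alive_start``, ``t2dm_start`` are (horizon, n); ``rf_end`` maps each
    continuous factor to (horizon, n).  ``t2dm_onset_year[i]`` is the year
    index at whose start patient *i* was first in the diabetic state (0 for
    baseline diabetes, -1 if never); ``death_year[i]`` the cycle in which
    the patient died (-1 if censored by the horizon).
    """

    def __init__(self, n: int, horizon: int, female: np.ndarray,
                 baseline_age: np.ndarray, patient_ids: np.ndarray):
        self.n = n
        self.horizon = horizon
        self.female = female
        self.baseline_age = baseline_age
        self.patient_ids = patient_ids
        E = len(EVENT_ORDER)
        self.events = np.zeros((horizon, n, E), dtype=bool)
        self.died = np.zeros((horizon, n), dtype=bool)
        self.alive_start = np.zeros((horizon, n), dtype=bool)
        self.t2dm_start = np.zeros((horizon, n), dtype=bool)
        self.jumped = np.zeros((horizon, n), dtype=bool)
        self.age_start = np.zeros((horizon, n), dtype=np.float32)
        self.rf_end = {}
        self.flags_end = {}
        self.t2dm_onset_year = np.full(n, -1, dtype=int)
        self.death_year = np.full(n, -1, dtype=int)

    # -- derived endpoint extraction ------------------------------------

    def first_event_year(self, endpoint: str) -> np.ndarray:
        """First occurrence time (in whole years, 1-based) per patient.

        For comorbidities the event in cycle ``t`` is timed at ``t + 1``;
        the diabetes-onset pseudo-endpoint is timed at the year index at
        whose start the patient first carried the T2DM classification.
        Returns -1 where the endpoint never occurs.
        """
        if endpoint == "death":
            out = np.where(self.death_year >= 0, self.death_year + 1, -1)
            return out
        if endpoint == "t2dm_onset":
            return self.t2dm_onset_year.copy()
        e = _EIDX[endpoint]
        occ = self.events[:, :, e]
        any_occ = occ.any(axis=0)
        first = occ.argmax(axis=0) + 1
        return np.where(any_occ, first, -1)

    def censor_year(self) -> np.ndarray:
        """Follow-up end per patient: death year + 1, else the horizon."""
        return np.where(self.death_year >= 0, self.death_year + 1,
                        self.horizon)

    def person_years(self) -> float:
        return float(self.alive_start.sum())

    def to_trajectories(self) -> list[Trajectory]:
        """Materialise per-patient records (intended for small cohorts)."""
        out = []
        for i in range(self.n):
            hist = EventHistory()
            records = []
            for t in range(self.horizon):
                if not self.alive_start[t, i]:
                    break
                evs = {EVENT_ORDER[e] for e in range(len(EVENT_ORDER))
                       if self.events[t, i, e]}
                in_t2dm = bool(self.t2dm_start[t, i])
                for ev in evs:
                    if ev in CHRONIC_EVENTS or ev == "ULCER":
                        hist.chronic_flags[ev] = True
                    elif in_t2dm:
                        hist.acute_counts[ev] += 1
                    else:
                        hist.pre_t2dm_acute_used[ev] = True
                rf = RiskFactorVector(
                    **{f: float(self.rf_end[f][t, i])
                       for f in _UPDATED_CONTINUOUS},
                    **{f: bool(self.flags_end[f][t, i])
                       for f in ("albuminuria", "pvd", "af", "lvh", "smoker")},
                )
                records.append(AnnualRecord(
                    year_index=t,
                    state_at_start=T2DM if in_t2dm else NGT_PRE,
                    events=evs,
                    died=bool(self.died[t, i]),
                    risk_factors_end=rf,
                    age_at_start=float(self.age_start[t, i]),
                ))
            out.append(Trajectory(
                patient_id=int(self.patient_ids[i]), records=records,
                death_year=(int(self.death_year[i])
                            if self.death_year[i] >= 0 else None),
                female=bool(self.female[i]),
                baseline_age=float(self.baseline_age[i]),
            ))
        return out


# --------------------------------------------------------------------------
# operations


def randomize_event_order(applicable_events: list, rng: np.random.Generator):
    """Uniform random permutation of the candidate event list."""
    events = list(applicable_events)
    if not events:
        return []
    perm = rng.permutation(len(events))
    return [events[j] for j in perm]


def _make_ctx(age, female, duration, rf, flags, hist, cur):
    ctx = {
        "age": age, "female": female.astype(float),
        "male": 1.0 - female.astype(float), "duration": duration,
    }
    ctx.update(rf)
    for k, v in flags.items():
        ctx[k] = v.astype(float)
    for ev in EVENT_ORDER:
        ctx[f"hist_{ev.lower()}"] = hist[ev].astype(float)
        ctx[f"event_{ev.lower()}"] = cur[ev].astype(float)
    return ctx


def simulate_cohort(cohort: Cohort, params, horizon: int, seed: int,
                    intervention=None, compliant: np.ndarray | None = None,
                    start_year: int = 0,
                    initial_history: EventHistory | None = None
                    ) -> CohortResult:
    """Simulate every patient for up to ``horizon`` years.

    ``params`` is a :class:`~t2dsim.psa.ParameterSet` or a bare
    :class:`~t2dsim.risk_models.CoefficientTable`.  ``intervention`` is an
    optional :class:`~t2dsim.intervention.InterventionSpec` with a boolean
    ``compliant`` flag per patient; effects apply to compliant patients who
    have not yet developed diabetes, during the programme years.

    Each patient's randomness is addressed by (seed, patient id, year,
    purpose), so the result is independent of cohort ordering and identical
    per patient whether simulated alone or in a batch.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    table: CoefficientTable = getattr(params, "coefficients", params)
    n = len(cohort)
    ids = getattr(cohort, "patient_ids", np.arange(n))
    female = cohort.columns["female"].astype(bool).copy() if n else np.zeros(0, bool)
    age = cohort.columns["age"].astype(float).copy() if n else np.zeros(0)
    res = CohortResult(n, horizon, female, age.copy(), np.asarray(ids))
    if n == 0:
        res.rf_end = {f: np.zeros((horizon, 0)) for f in _UPDATED_CONTINUOUS}
        res.flags_end = {f: np.zeros((horizon, 0), bool)
                         for f in ("albuminuria", "pvd", "af", "lvh", "smoker")}
        return res

    keys = streams.keys_for_ids(seed, "sim", np.asarray(ids))
    rf = {f: cohort.columns[f].astype(float).copy()
          for f in _UPDATED_CONTINUOUS}
    flags = {f: cohort.columns[f].astype(bool).copy()
             for f in ("albuminuria", "pvd", "af", "lvh", "smoker")}
    t2dm = (np.asarray(cohort.state) == T2DM).copy()
    duration = cohort.years_since_t2dm.astype(float).copy()
    alive = np.ones(n, dtype=bool)

    chronic = {ev: np.zeros(n, dtype=bool)
               for ev in CHRONIC_EVENTS + ("ULCER",)}
    acute = {ev: np.zeros(n, dtype=int) for ev in ACUTE_EVENTS}
    ngt_used = {ev: np.zeros(n, dtype=bool) for ev in ("MI", "STROKE")}
    if initial_history is not None:
        for ev, v in initial_history.chronic_flags.items():
            chronic[ev][:] = bool(v)
        for ev, v in initial_history.acute_counts.items():
            acute[ev][:] = int(v)
        for ev, v in initial_history.pre_t2dm_acute_used.items():
            ngt_used[ev][:] = bool(v)

    def hist_flags():
        h = {}
        for ev in EVENT_ORDER:
            f = chronic.get(ev, None)
            if f is None:
                f = acute[ev] > 0
                if ev in ngt_used:
                    f = f | ngt_used[ev]
            h[ev] = f
        return h

    res.rf_end = {f: np.zeros((horizon, n)) for f in _UPDATED_CONTINUOUS}
    res.flags_end = {f: np.zeros((horizon, n), dtype=bool) for f in flags}

    bounds = table.bounds
    tp = table.transition
    spec = intervention
    if spec is not None and compliant is None:
        raise ValueError("intervention requires per-patient compliance flags")

    for t in range(horizon):
        tg = start_year + t       # absolute cycle index for stream counters
        res.alive_start[t] = alive
        res.t2dm_start[t] = t2dm & alive
        res.age_start[t] = age
        newly = t2dm & alive & (res.t2dm_onset_year < 0)
        res.t2dm_onset_year[newly] = t
        if not alive.any():
            break

        any_history = np.zeros(n, dtype=bool)
        for ev in EVENT_ORDER:
            any_history |= hist_flags()[ev]

        cur = {ev: np.zeros(n, dtype=bool) for ev in EVENT_ORDER}
        hist = hist_flags()
        ctx = _make_ctx(age, female, duration, rf, flags, hist, cur)

        # --- events in randomised order --------------------------------
        perm_u = np.empty((n, len(EVENT_ORDER)))
        for j in range(len(EVENT_ORDER)):
            perm_u[:, j] = streams.uniforms(keys, _P_PERM, tg, j)
        perm = np.argsort(perm_u, axis=1, kind="stable")

        # eligibility at year start
        elig = np.zeros((n, len(EVENT_ORDER)), dtype=bool)
        for ev, e in _EIDX.items():
            if ev in CHRONIC_EVENTS:
                ok_t2 = ~chronic[ev]
                ok_ngt = (ev in _NGT_SET) & ~chronic[ev]
            elif ev == "ULCER":
                ok_t2 = ~chronic[ev] if table.ulcer_chronic else np.ones(n, bool)
                ok_ngt = False
            else:  # acute
                total = acute[ev].copy()
                if getattr(table, "carry_acute_across_states", False) \
                        and ev in ngt_used:
                    total = total + ngt_used[ev].astype(int)
                ok_t2 = total < 2
                ok_ngt = (ev in _NGT_SET) and ~ngt_used.get(
                    ev, np.zeros(n, bool))
            elig[:, e] = np.where(t2dm, ok_t2, ok_ngt) & alive

        event_u = {e: None for e in range(len(EVENT_ORDER))}
        for r in range(len(EVENT_ORDER)):
            ev_at_rank = perm[:, r]
            for ev, e in _EIDX.items():
                mask = alive & (ev_at_rank == e) & elig[:, e]
                if not mask.any():
                    continue
                if event_u[e] is None:
                    event_u[e] = streams.uniforms(keys, _P_EVENT, tg, e)
                u = event_u[e]
                occurred = np.zeros(n, dtype=bool)
                m_t2 = mask & t2dm
                m_ngt = mask & ~t2dm
                if m_t2.any():
                    if ev in ACUTE_EVENTS:
                        prior = acute[ev]
                        for pc, tag in ((0, "1"), (1, "2")):
                            sub = m_t2 & (prior == pc)
                            if sub.any():
                                eq = table.event_equations[
                                    f"t2dm_{ev.lower()}{tag}"]
                                p = eq.probability(ctx)
                                occurred |= sub & (u < p)
                    else:
                        eq = table.event_equations[f"t2dm_{ev.lower()}"]
                        p = eq.probability(ctx)
                        occurred |= m_t2 & (u < p)
                if m_ngt.any():
                    eq = table.event_equations[f"ngt_{ev.lower()}"]
                    p = eq.probability(ctx)
                    occurred |= m_ngt & (u < p)
                if not occurred.any():
                    continue
                res.events[t, occurred, e] = True
                cur[ev][occurred] = True
                ctx[f"event_{ev.lower()}"] = cur[ev].astype(float)
                if ev in chronic and (ev in CHRONIC_EVENTS
                                      or table.ulcer_chronic):
                    chronic[ev][occurred] = True
                if ev in ACUTE_EVENTS:
                    inc_t2 = occurred & t2dm
                    acute[ev][inc_t2] += 1
                    if ev in ngt_used:
                        ngt_used[ev][occurred & ~t2dm] = True
                # refresh history view for later same-year equations
                hist = hist_flags()
                ctx[f"hist_{ev.lower()}"] = hist[ev].astype(float)

        # --- mortality --------------------------------------------------
        new_events = np.zeros(n, dtype=bool)
        for ev in EVENT_ORDER:
            new_events |= cur[ev]
        p_mort = np.zeros(n)
        for any_h in (False, True):
            for new_e in (False, True):
                m = alive & t2dm & (any_history == any_h) & (new_events == new_e)
                if m.any():
                    eq = table.mortality_equations[
                        select_mortality_equation(any_h, new_e)]
                    p_mort = np.where(m, np.clip(eq.probability(ctx), 0, 1),
                                      p_mort)
        m_ngt = alive & ~t2dm
        if m_ngt.any():
            ev_year = m_ngt & new_events
            if ev_year.any():
                cf = np.zeros((len(NGT_EVENTS), n))
                present = np.zeros((len(NGT_EVENTS), n), dtype=bool)
                for k, ev in enumerate(NGT_EVENTS):
                    cf[k] = table.ngt_mortality.case_fatality[ev].lookup(
                        age, female)
                    present[k] = cur[ev]
                if table.ngt_mortality.combination == "max":
                    p_ev = np.where(present, cf, -np.inf).max(axis=0)
                else:
                    logs = np.where(
                        present,
                        np.log1p(-np.clip(cf, 0.0, 1 - 1e-12)), 0.0)
                    p_ev = -np.expm1(logs.sum(axis=0))
                p_mort = np.where(ev_year, p_ev, p_mort)
            no_ev = m_ngt & ~new_events
            if no_ev.any():
                p_bg = ngt_background_mortality(table, age, female)
                p_mort = np.where(no_ev, p_bg, p_mort)
        u_m = streams.uniforms(keys, _P_MORT, tg, 0)
        dies = alive & (u_m < p_mort)
        res.died[t, dies] = True
        res.death_year[dies] = t
        alive = alive & ~dies

        # --- end-of-year risk-factor updates (survivors) ----------------
        sv = alive
        hist = hist_flags()
        ctx = _make_ctx(age, female, duration, rf, flags, hist, cur)
        new_rf = {}
        for factor in _UPDATED_CONTINUOUS:
            if factor == "hba1c":
                continue
            try:
                eq_both = table.risk_factor_equations[f"{factor}@both"]
            except KeyError:
                eq_both = table.risk_factor_equations.get(factor)
            if eq_both is not None:
                val = eq_both.update(ctx)
            else:
                v_t2 = table.risk_factor_equation(factor, T2DM).update(ctx)
                v_ngt = table.risk_factor_equation(factor, NGT_PRE).update(ctx)
                val = np.where(t2dm, v_t2, v_ngt)
            new_rf[factor] = val

        h_t2 = table.risk_factor_equation("hba1c", T2DM).update(ctx)
        h_ngt = table.risk_factor_equation("hba1c", NGT_PRE).update(ctx)
        band = sv & ~t2dm & in_pre_t2dm_band(rf["hba1c"])
        p_jump = np.full(n, tp.p_jump)
        active = np.zeros(n, dtype=bool)
        if spec is not None and t < spec.duration:
            active = compliant & ~t2dm
            p_jump = np.where(active, tp.p_jump * spec.jump_multiplier, p_jump)
        u_j = streams.uniforms(keys, _P_JUMP, tg, 0)
        jump = band & (u_j < p_jump)
        res.jumped[t] = jump
        new_h = np.where(jump, rf["hba1c"] + tp.delta_hba1c, h_ngt)
        if spec is not None and t < spec.duration:
            shift_b, shift_h = spec.effect_at(t)
            new_rf["bmi"] = np.where(active, new_rf["bmi"] + shift_b,
                                     new_rf["bmi"])
            new_h = np.where(active & ~jump, new_h + shift_h, new_h)
        new_rf["hba1c"] = np.where(t2dm, h_t2, new_h)

        for factor, val in new_rf.items():
            lo, hi = bounds.get(factor, (-np.inf, np.inf))
            rf[factor] = np.where(sv, np.clip(val, lo, hi), rf[factor])

        for j, factor in enumerate(_BINARY_PROG):
            eq = None
            for key in (f"{factor}@{T2DM}", f"{factor}@both", factor):
                if key in table.binary_incidence_equations:
                    eq = table.binary_incidence_equations[key]
                    break
            key_ngt = f"{factor}@{NGT_PRE}"
            p = eq.probability(ctx) if eq is not None else np.zeros(n)
            if key_ngt in table.binary_incidence_equations:
                p_ngt = table.binary_incidence_equations[key_ngt].probability(ctx)
                p = np.where(t2dm, p, p_ngt)
            u = streams.uniforms(keys, _P_BIN, tg, j)
            flags[factor] = flags[factor] | (sv & (u < p))
        p_lvh = table.lvh_equation.probability(ctx)
        if table.lvh_mode == "threshold":
            new_lvh = p_lvh >= 0.5
        else:
            u = streams.uniforms(keys, _P_LVH, tg, 0)
            new_lvh = u < p_lvh
        flags["lvh"] = flags["lvh"] | (sv & new_lvh)

        for f in _UPDATED_CONTINUOUS:
            res.rf_end[f][t] = rf[f]
        for f in flags:
            res.flags_end[f][t] = flags[f]

        age = np.where(sv, age + 1.0, age)
        duration = np.where(sv & t2dm, duration + 1.0, duration)
        t2dm = t2dm | (sv & (rf["hba1c"] >= T2DM_THRESHOLD))

    return res


def simulate_patient(patient: PatientState, params, horizon: int,
                     seed: int) -> Trajectory:
    """Simulate a single patient; equivalent to a cohort of one."""
    cohort = Cohort.from_patients([patient])
    res = simulate_cohort(cohort, params, horizon, seed,
                          initial_history=patient.history)
    return res.to_trajectories()[0]


def simulate_year(patient: PatientState, params, seed: int,
                  year_index: int = 0) -> AnnualRecord:
    """Simulate one annual cycle for one patient.

    The patient object is advanced in place (age, risk factors, history,
    state and ``alive``), so repeated calls with increasing ``year_index``
    reproduce :func:`simulate_patient` cycle by cycle.
    """
    if not patient.alive:
        raise StateError("cannot simulate a year for a dead patient")
    cohort = Cohort.from_patients([patient])
    res = simulate_cohort(cohort, params, 1, seed, start_year=year_index,
                          initial_history=patient.history)
    traj = res.to_trajectories()[0]
    rec = traj.records[0]
    rec.year_index = year_index
    # advance the caller's patient
    if patient.history is None:
        patient.history = EventHistory()
    hist = patient.history
    in_t2dm = rec.state_at_start == T2DM
    for ev in rec.events:
        if ev in CHRONIC_EVENTS or ev == "ULCER":
            hist.chronic_flags[ev] = True
        elif in_t2dm:
            hist.acute_counts[ev] += 1
        else:
            hist.pre_t2dm_acute_used[ev] = True
    hist.current_year_events = set(rec.events)
    patient.risk_factors = rec.risk_factors_end
    if rec.died:
        patient.alive = False
    else:
        patient.age += 1
        if in_t2dm:
            patient.years_since_t2dm += 1
        patient.state = (T2DM if in_t2dm
                         or rec.risk_factors_end.hba1c >= T2DM_THRESHOLD
                         else NGT_PRE)
    return rec
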