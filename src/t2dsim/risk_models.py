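"""Per-cycle risk equations.

Every annual probability and risk-factor update in the model is expressed as
an :class:`EquationSpec` — a functional form plus a named coefficient map —
loaded from configuration.  The forms cover the algebra used by the model's
sources:

* proportional-hazard forms (exponential, Weibull on diabetes duration,
  Gompertz on current age), converted to an annual probability by
  integrating the hazard over the one-year cycle:
  ``p = 1 - exp(-H(t, t+1))``;
* logistic regressions for event-year probabilities and binary risk-factor
  incidence;
* linear / autoregressive updates for continuous risk-factor progression;
* age- and sex-indexed lookup tables for pre-diabetes background and
  event-specific mortality.

Patients with diagnosed diabetes face eight comorbidities (CHF, IHD,
blindness, renal failure, MI, stroke, amputation, diabetic ulcer) and one of
four mutually exclusive mortality equations chosen by whether the patient
has a history of comorbidities and whether any occurred in the current year.
Patients before diagnosis face three comorbidities (MI, CHF, stroke),
event-table mortality in event years and cause-deleted background mortality
otherwise, and — while their HbA1c is in the pre-diabetes band — a
configured probability ``p_jump`` (default 0.129) of a sudden HbA1c rise of
``delta_hba1c`` (default 0.54 percentage points) that takes them into the
diabetic state.

All evaluation functions are vectorised over patients via a *context*: a
mapping from predictor name to a numpy array (risk factors, demographics,
diabetes duration, history flags ``hist_*`` and current-year event
indicators ``event_*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from .cohort import (
    NGT_PRE, T2DM, PatientState, RiskFactorVector, in_pre_t2dm_band,
)
from .errors import ConfigurationError, StateError

# canonical comorbidity names
MI, STROKE, CHF, IHD = "MI", "STROKE", "CHF", "IHD"
BLINDNESS, RENAL_FAILURE, AMPUTATION, ULCER = (
    "BLINDNESS", "RENAL_FAILURE", "AMPUTATION", "ULCER"
)
T2DM_EVENTS = (CHF, IHD, BLINDNESS, RENAL_FAILURE, MI, STROKE, AMPUTATION, ULCER)
NGT_EVENTS = (MI, CHF, STROKE)
CHRONIC_EVENTS = (CHF, IHD, BLINDNESS, RENAL_FAILURE)   # + ULCER if configured
ACUTE_EVENTS = (MI, STROKE, AMPUTATION)

HAZARD_FORMS = ("exponential_hazard", "weibull_hazard", "gompertz_hazard")
FORMS = HAZARD_FORMS + (
    "logistic", "linear_update", "autoregressive_update", "lookup_table"
)

#: event-equation keys that must be present in every coefficient table
REQUIRED_EVENT_EQUATIONS = (
    "ngt_mi", "ngt_chf", "ngt_stroke",
    "t2dm_chf", "t2dm_ihd", "t2dm_blindness", "t2dm_renal_failure",
    "t2dm_mi1", "t2dm_mi2", "t2dm_stroke1", "t2dm_stroke2",
    "t2dm_amputation1", "t2dm_amputation2", "t2dm_ulcer",
)
REQUIRED_MORTALITY_EQUATIONS = (
    "mort_nohist_noevent", "mort_nohist_event",
    "mort_hist_noevent", "mort_hist_event",
)

#: default truncation bounds applied after risk-factor updates
DEFAULT_BOUNDS = {
    "hba1c": (3.5, 18.0), "bmi": (12.0, 70.0), "sbp": (70.0, 240.0),
    "ldl": (0.3, 10.0), "hdl": (0.3, 4.0), "egfr": (2.0, 160.0),
    "haem": (6.0, 20.0), "wbc": (1.0, 30.0), "heart_rate": (35.0, 180.0),
}


@dataclass
class EquationSpec:
    """One model equation: functional form + named coefficients.

    ``coefficients`` maps predictor names to values and must contain an
    ``intercept`` entry (the constant term; for hazard forms this is the log
    baseline cumulative hazard over the first cycle).  ``shape`` is the
    Weibull shape or Gompertz slope.  ``time_scale`` selects the hazard's
    time axis: ``duration`` (years since diabetes onset) or ``age``.
    ``transforms`` optionally recodes predictors before multiplication:
    ``{center: v}``, ``{scale: v}``, ``{hinge: v}`` (= max(x - v, 0)) or
    ``{indicator: v}`` (= 1 if x > v).
    """

    name: str
    form: str
    coefficients: Mapping[str, float]
    transforms: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    applicable_state: str = "both"          # NGT_PRE | T2DM | both
    shape: float | None = None
    time_scale: str = "duration"
    source: str = ""

    def validate(self) -> None:
        if self.form not in FORMS:
            raise ConfigurationError(
                f"equation {self.name!r}: unknown form {self.form!r}"
            )
        if "intercept" not in self.coefficients:
            raise ConfigurationError(
                f"equation {self.name!r}: coefficients must include 'intercept'"
            )
        if self.form in ("weibull_hazard", "gompertz_hazard") and self.shape is None:
            raise ConfigurationError(
                f"equation {self.name!r}: {self.form} requires a shape parameter"
            )
        if self.time_scale not in ("duration", "age"):
            raise ConfigurationError(
                f"equation {self.name!r}: time_scale must be duration or age"
            )
        for pred, tr in self.transforms.items():
            for key in tr:
                if key not in ("center", "scale", "hinge", "indicator"):
                    raise ConfigurationError(
                        f"equation {self.name!r}: unknown transform {key!r} "
                        f"on predictor {pred!r}"
                    )

    # -- evaluation ------------------------------------------------------

    def _predictor(self, name: str, ctx: Mapping[str, np.ndarray]) -> np.ndarray:
        try:
            x = np.asarray(ctx[name], dtype=float)
        except KeyError:
            raise ConfigurationError(
                f"equation {self.name!r}: predictor {name!r} not available "
                "in the patient context"
            ) from None
        tr = self.transforms.get(name)
        if tr:
            if "center" in tr:
                x = x - tr["center"]
            if "scale" in tr:
                x = x / tr["scale"]
            if "hinge" in tr:
                x = np.maximum(x - tr["hinge"], 0.0)
            if "indicator" in tr:
                x = (x > tr["indicator"]).astype(float)
        return x

    def linear_predictor(self, ctx: Mapping[str, np.ndarray]) -> np.ndarray:
        lp = None
        for name, coef in self.coefficients.items():
            if name == "intercept":
                continue
            term = coef * self._predictor(name, ctx)
            lp = term if lp is None else lp + term
        const = float(self.coefficients["intercept"])
        if lp is None:
            n = len(np.asarray(ctx["age"], dtype=float))
            return np.full(n, const)
        return lp + const

    def cycle_cumulative_hazard(self, ctx: Mapping[str, np.ndarray]) -> np.ndarray:
        """Hazard integrated over the coming one-year cycle."""
        lp = self.linear_predictor(ctx)
        if self.form == "exponential_hazard":
            return np.exp(lp)
        t0 = np.asarray(
            ctx["duration" if self.time_scale == "duration" else "age"],
            dtype=float,
        )
        if self.form == "weibull_hazard":
            rho = float(self.shape)
            return np.exp(lp) * ((t0 + 1.0) ** rho - t0 ** rho)
        if self.form == "gompertz_hazard":
            phi = float(self.shape)
            if phi == 0.0:
                return np.exp(lp)
            return np.exp(lp) * (np.exp(phi * (t0 + 1.0)) - np.exp(phi * t0)) / phi
        raise ConfigurationError(f"{self.name}: not a hazard form")

    def probability(self, ctx: Mapping[str, np.ndarray]) -> np.ndarray:
        """Annual event probability for hazard/logistic forms."""
        if self.form in HAZARD_FORMS:
            return -np.expm1(-self.cycle_cumulative_hazard(ctx))
        if self.form == "logistic":
            return expit(self.linear_predictor(ctx))
        raise ConfigurationError(
            f"equation {self.name!r} ({self.form}) does not define a probability"
        )

    def update(self, ctx: Mapping[str, np.ndarray]) -> np.ndarray:
        """Next-cycle value for linear/autoregressive update forms."""
        if self.form not in ("linear_update", "autoregressive_update"):
            raise ConfigurationError(
                f"equation {self.name!r} ({self.form}) is not an update form"
            )
        return self.linear_predictor(ctx)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "form": self.form,
            "coefficients": dict(self.coefficients),
        }
        if self.transforms:
            d["transforms"] = {k: dict(v) for k, v in self.transforms.items()}
        if self.applicable_state != "both":
            d["applicable_state"] = self.applicable_state
        if self.shape is not None:
            d["shape"] = self.shape
        if self.time_scale != "duration":
            d["time_scale"] = self.time_scale
        if self.source:
            d["source"] = self.source
        return d

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "EquationSpec":
        try:
            eq = cls(
                name=name,
                form=d["form"],
                coefficients={k: float(v) for k, v in d["coefficients"].items()},
                transforms=d.get("transforms", {}),
                applicable_state=d.get("applicable_state", "both"),
                shape=d.get("shape"),
                time_scale=d.get("time_scale", "duration"),
                source=d.get("source", ""),
            )
        except KeyError as e:
            raise ConfigurationError(
                f"equation {name!r}: missing required key {e.args[0]!r}"
            ) from None
        eq.validate()
        return eq


@dataclass
class LookupTable:
    """Age-band x sex lookup (mortality probabilities or hazards)."""

    age_bands: np.ndarray          # ascending lower band edges
    male: np.ndarray
    female: np.ndarray
    boundary: str = "clamp"        # clamp | error

    def validate(self, name: str = "lookup") -> None:
        if not (len(self.age_bands) == len(self.male) == len(self.female)):
            raise ConfigurationError(f"{name}: band/value length mismatch")
        if np.any(np.diff(self.age_bands) <= 0):
            raise ConfigurationError(f"{name}: age bands must be ascending")

    def lookup(self, age: np.ndarray, female: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.boundary == "error" and np.any(age < self.age_bands[0]):
            raise ConfigurationError(
                f"age below first lookup band ({self.age_bands[0]})"
            )
        idx = np.clip(
            np.searchsorted(self.age_bands, age, side="right") - 1,
            0, len(self.age_bands) - 1,
        )
        fem = np.asarray(female, dtype=bool)
        return np.where(fem, np.asarray(self.female)[idx],
                        np.asarray(self.male)[idx])

    def to_dict(self) -> dict:
        return {
            "age_bands": [float(x) for x in self.age_bands],
            "male": [float(x) for x in self.male],
            "female": [float(x) for x in self.female],
            "boundary": self.boundary,
        }

    @classmethod
    def from_dict(cls, d: Mapping, name: str = "lookup") -> "LookupTable":
        try:
            t = cls(
                age_bands=np.asarray(d["age_bands"], dtype=float),
                male=np.asarray(d["male"], dtype=float),
                female=np.asarray(d["female"], dtype=float),
                boundary=d.get("boundary", "clamp"),
            )
        except KeyError as e:
            raise ConfigurationError(
                f"{name}: missing required key {e.args[0]!r}"
            ) from None
        t.validate(name)
        return t


@dataclass
class TransitionParams:
    """Pre-diabetes sudden-rise transition parameters."""

    p_jump: float = 0.129
    delta_hba1c: float = 0.54

    def validate(self) -> None:
        if not 0.0 <= self.p_jump <= 1.0:
            raise ConfigurationError("transition.p_jump must be in [0, 1]")
        if self.delta_hba1c <= 0:
            raise ConfigurationError("transition.delta_hba1c must be > 0")


@dataclass
class NgtMortalityTables:
    """Pre-diabetes-layer mortality inputs.

    ``background`` holds annual all-cause death probabilities by age/sex;
    ``cause_removal`` the cumulative-hazard component attributable to MI,
    CHF and stroke (removed from the background in event-free years because
    those causes are modelled explicitly); ``case_fatality`` the one-year
    all-cause death probability following each comorbidity.
    """

    background: LookupTable
    cause_removal: LookupTable
    case_fatality: Mapping[str, LookupTable]
    combination: str = "max"        # max | complement_product

    def validate(self) -> None:
        for ev in NGT_EVENTS:
            if ev not in self.case_fatality:
                raise ConfigurationError(
                    f"ngt mortality: missing case_fatality table for {ev}"
                )
        if self.combination not in ("max", "complement_product"):
            raise ConfigurationError(
                "ngt mortality combination must be max or complement_product"
            )


@dataclass
class CoefficientTable:
    """Complete set of model equations and transition parameters."""

    event_equations: dict[str, EquationSpec]
    mortality_equations: dict[str, EquationSpec]
    risk_factor_equations: dict[str, EquationSpec]    # key "<factor>@<state>"
    binary_incidence_equations: dict[str, EquationSpec]
    lvh_equation: EquationSpec
    ngt_mortality: NgtMortalityTables
    transition: TransitionParams = field(default_factory=TransitionParams)
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    lvh_mode: str = "bernoulli"     # bernoulli | threshold
    ulcer_chronic: bool = True

    def validate(self) -> None:
        for key in REQUIRED_EVENT_EQUATIONS:
            if key not in self.event_equations:
                raise ConfigurationError(f"missing event equation {key!r}")
        for key in REQUIRED_MORTALITY_EQUATIONS:
            if key not in self.mortality_equations:
                raise ConfigurationError(f"missing mortality equation {key!r}")
        for eq in self._all_equations():
            eq.validate()
        self.ngt_mortality.validate()
        self.transition.validate()
        if self.lvh_mode not in ("bernoulli", "threshold"):
            raise ConfigurationError("lvh_mode must be bernoulli or threshold")

    def _all_equations(self):
        yield from self.event_equations.values()
        yield from self.mortality_equations.values()
        yield from self.risk_factor_equations.values()
        yield from self.binary_incidence_equations.values()
        yield self.lvh_equation

    def risk_factor_equation(self, factor: str, state: str) -> EquationSpec:
        for key in (f"{factor}@{state}", f"{factor}@both", factor):
            if key in self.risk_factor_equations:
                return self.risk_factor_equations[key]
        raise ConfigurationError(
            f"no progression equation for risk factor {factor!r} "
            f"in state {state}"
        )

    def event_equation_key(self, event: str, state: str,
                           prior_count: int = 0) -> str:
        """Resolve a canonical event + state (+ occurrence index) to a key."""
        if state == NGT_PRE:
            if event not in NGT_EVENTS:
                raise StateError(
                    f"event {event} is not modelled in the {NGT_PRE} state"
                )
            return f"ngt_{event.lower()}"
        if event not in T2DM_EVENTS:
            raise StateError(f"unknown T2DM event {event}")
        if event in ACUTE_EVENTS:
            return f"t2dm_{event.lower()}{min(prior_count, 1) + 1}"
        return f"t2dm_{event.lower()}"

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "event_equations": {k: v.to_dict()
                                for k, v in self.event_equations.items()},
            "mortality_equations": {k: v.to_dict()
                                    for k, v in self.mortality_equations.items()},
            "risk_factor_equations": {k: v.to_dict()
                                      for k, v in self.risk_factor_equations.items()},
            "binary_incidence_equations": {
                k: v.to_dict()
                for k, v in self.binary_incidence_equations.items()},
            "lvh_equation": self.lvh_equation.to_dict(),
            "lvh_mode": self.lvh_mode,
            "ulcer_chronic": self.ulcer_chronic,
            "ngt_mortality": {
                "background": self.ngt_mortality.background.to_dict(),
                "cause_removal": self.ngt_mortality.cause_removal.to_dict(),
                "case_fatality": {k: v.to_dict()
                                  for k, v in
                                  self.ngt_mortality.case_fatality.items()},
                "combination": self.ngt_mortality.combination,
            },
            "transition": {"p_jump": self.transition.p_jump,
                           "delta_hba1c": self.transition.delta_hba1c},
            "bounds": {k: [float(v[0]), float(v[1])]
                       for k, v in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientTable":
        def eqs(block_name):
            block = d.get(block_name)
            if block is None:
                raise ConfigurationError(f"missing config block {block_name!r}")
            return {k: EquationSpec.from_dict(k, v) for k, v in block.items()}

        ngt = d.get("ngt_mortality")
        if ngt is None:
            raise ConfigurationError("missing config block 'ngt_mortality'")
        table = cls(
            event_equations=eqs("event_equations"),
            mortality_equations=eqs("mortality_equations"),
            risk_factor_equations=eqs("risk_factor_equations"),
            binary_incidence_equations=eqs("binary_incidence_equations"),
            lvh_equation=EquationSpec.from_dict(
                "lvh", d.get("lvh_equation", {})),
            ngt_mortality=NgtMortalityTables(
                background=LookupTable.from_dict(
                    ngt["background"], "ngt background mortality"),
                cause_removal=LookupTable.from_dict(
                    ngt["cause_removal"], "ngt cause removal"),
                case_fatality={k: LookupTable.from_dict(v, f"case fatality {k}")
                               for k, v in ngt["case_fatality"].items()},
                combination=ngt.get("combination", "max"),
            ),
            transition=TransitionParams(
                p_jump=float(d.get("transition", {}).get("p_jump", 0.129)),
                delta_hba1c=float(
                    d.get("transition", {}).get("delta_hba1c", 0.54)),
            ),
            bounds={k: (float(v[0]), float(v[1]))
                    for k, v in d.get("bounds", DEFAULT_BOUNDS).items()},
            lvh_mode=d.get("lvh_mode", "bernoulli"),
            ulcer_chronic=bool(d.get("ulcer_chronic", True)),
        )
        table.validate()
        return table


# --------------------------------------------------------------------------
# patient context


def patient_context(patient: PatientState) -> dict[str, np.ndarray]:
    """Length-1 context arrays for a single patient."""
    rf = patient.risk_factors
    ctx = {
        "age": np.array([patient.age]),
        "female": np.array([float(patient.female)]),
        "male": np.array([float(not patient.female)]),
        "duration": np.array([float(patient.years_since_t2dm)]),
    }
    for name in ("hba1c", "bmi", "sbp", "ldl", "hdl", "egfr", "haem",
                 "wbc", "heart_rate"):
        ctx[name] = np.array([float(getattr(rf, name))])
    for name in ("albuminuria", "pvd", "af", "lvh", "smoker"):
        ctx[name] = np.array([float(getattr(rf, name))])
    hist = patient.history
    for ev in T2DM_EVENTS:
        flag = 0.0
        cur = 0.0
        if hist is not None:
            flag = float(hist.ever(ev))
            cur = float(ev in hist.current_year_events)
        ctx[f"hist_{ev.lower()}"] = np.array([flag])
        ctx[f"event_{ev.lower()}"] = np.array([cur])
    return ctx


# --------------------------------------------------------------------------
# operations (per-patient surface over the vectorised cores)


def annual_event_probability(patient: PatientState, event: str,
                             table: CoefficientTable) -> float:
    """Annual probability of ``event`` for one patient in their state."""
    if not patient.alive:
        raise StateError("patient is not alive")
    prior = 0
    if patient.history is not None and event in ACUTE_EVENTS:
        prior = patient.history.acute_counts.get(event, 0)
    key = table.event_equation_key(event, patient.state, prior)
    eq = table.event_equations[key]
    return float(eq.probability(patient_context(patient))[0])


def pre_t2dm_event_probability(patient: PatientState, event: str,
                               table: CoefficientTable) -> float:
    """Annual probability of MI/CHF/stroke before diabetes onset."""
    if patient.state != NGT_PRE:
        raise StateError(
            f"pre-diabetes event probability requested for a {patient.state} "
            "patient"
        )
    return annual_event_probability(patient, event, table)


def apply_hba1c_jump(patient: PatientState, u: float,
                     table: CoefficientTable) -> tuple[float, bool]:
    """Resolve the pre-diabetes sudden-rise transition for one patient.

    With probability ``p_jump`` HbA1c rises by ``delta_hba1c`` (crossing into
    the diabetic range); otherwise the ordinary HbA1c progression equation
    applies.
    """
    hba1c = patient.risk_factors.hba1c
    if not in_pre_t2dm_band(hba1c):
        raise StateError(
            f"HbA1c {hba1c} is outside the pre-diabetes band"
        )
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    if u < table.transition.p_jump:
        return hba1c + table.transition.delta_hba1c, True
    eq = table.risk_factor_equation("hba1c", NGT_PRE)
    return float(eq.update(patient_context(patient))[0]), False


def update_risk_factors(patient: PatientState, table: CoefficientTable,
                        rng: np.random.Generator | None = None
                        ) -> RiskFactorVector:
    """End-of-cycle risk-factor update for one patient.

    Continuous factors are replaced by their progression-equation outputs
    (each may depend on the other current factors), then truncated to the
    configured physiologic bounds.  Binary factors progress by incidence
    draws (absorbing); without an ``rng`` they are left unchanged.  The
    jump transition is the engine's responsibility and is not applied here.
    """
    if not patient.alive:
        raise StateError("patient is not alive")
    ctx = patient_context(patient)
    state = patient.state
    new = {}
    for factor in ("hba1c", "bmi", "sbp", "ldl", "hdl", "egfr", "haem",
                   "wbc", "heart_rate"):
        eq = table.risk_factor_equation(factor, state)
        lo, hi = table.bounds.get(factor, (-np.inf, np.inf))
        new[factor] = float(np.clip(eq.update(ctx)[0], lo, hi))
    rf = patient.risk_factors
    flags = {name: getattr(rf, name)
             for name in ("albuminuria", "pvd", "af", "lvh", "smoker")}
    if rng is not None:
        for name, p in binary_incidence_probs(table, ctx, state).items():
            if not flags[name] and rng.uniform() < float(p[0]):
                flags[name] = True
        if not flags["lvh"]:
            flags["lvh"] = predict_lvh(patient, table,
                                       u=float(rng.uniform()))
    return RiskFactorVector(**new, **flags)


def binary_incidence_probs(table: CoefficientTable,
                           ctx: Mapping[str, np.ndarray],
                           state: str) -> dict[str, np.ndarray]:
    """Annual incidence probability for each progressing binary factor."""
    out = {}
    for key, eq in table.binary_incidence_equations.items():
        factor, _, eq_state = key.partition("@")
        if eq_state in ("", "both") or eq_state == state:
            if factor not in out or eq_state == state:
                out[factor] = eq.probability(ctx)
    return out


def predict_lvh(patient: PatientState, table: CoefficientTable,
                u: float | None = None) -> bool:
    """Left-ventricular-hypertrophy prediction for one patient."""
    if not patient.alive:
        raise StateError("patient is not alive")
    p = float(table.lvh_equation.probability(patient_context(patient))[0])
    if table.lvh_mode == "threshold":
        return p >= 0.5
    if u is None:
        raise ValueError("bernoulli LVH prediction requires a uniform draw")
    return u < p


def select_mortality_equation(any_history: bool,
                              new_events_this_year: bool) -> str:
    """Total selector over the 2x2 of (history, current-year events)."""
    if not any_history and not new_events_this_year:
        return "mort_nohist_noevent"       # (i)
    if not any_history and new_events_this_year:
        return "mort_nohist_event"         # (ii)
    if any_history and not new_events_this_year:
        return "mort_hist_noevent"         # (iii)
    return "mort_hist_event"               # (iv)


def t2dm_mortality_probability(patient: PatientState,
                               new_events_this_year: bool,
                               any_history: bool,
                               table: CoefficientTable) -> float:
    """Annual death probability in the diabetic state."""
    if patient.state != T2DM:
        raise StateError("T2DM mortality requested for a non-T2DM patient")
    key = select_mortality_equation(any_history, new_events_this_year)
    eq = table.mortality_equations[key]
    return float(np.clip(eq.probability(patient_context(patient))[0], 0.0, 1.0))


def ngt_event_year_mortality(table: CoefficientTable, events: set,
                             age: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Combine event-specific one-year mortality for same-year events."""
    probs = [table.ngt_mortality.case_fatality[ev].lookup(age, female)
             for ev in events]
    stacked = np.stack(probs, axis=0)
    if table.ngt_mortality.combination == "max":
        return stacked.max(axis=0)
    return -np.expm1(np.sum(np.log1p(-np.clip(stacked, 0.0, 1.0 - 1e-12)),
                            axis=0))


def ngt_background_mortality(table: CoefficientTable, age: np.ndarray,
                             female: np.ndarray) -> np.ndarray:
    """Background all-cause mortality with MI/CHF/stroke causes deleted.

    The deletion is on the cumulative-hazard scale:
    ``p = 1 - exp(-(H_all - c))`` with the removal floored so the adjusted
    hazard is never negative.
    """
    q = table.ngt_mortality.background.lookup(age, female)
    c = table.ngt_mortality.cause_removal.lookup(age, female)
    h = -np.log1p(-np.clip(q, 0.0, 1.0 - 1e-15))
    return -np.expm1(-np.maximum(h - c, 0.0))


def pre_t2dm_mortality_probability(patient: PatientState, events_this_year: set,
                                   table: CoefficientTable) -> float:
    """Annual death probability before diabetes onset."""
    if patient.state != NGT_PRE:
        raise StateError(
            "pre-diabetes mortality requested for a T2DM patient"
        )
    age = np.array([patient.age])
    fem = np.array([patient.female])
    if events_this_year:
        return float(ngt_event_year_mortality(table, events_this_year,
                                              age, fem)[0])
    return float(ngt_background_mortality(table, age, fem)[0])
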