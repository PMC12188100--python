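"""Costs, QALYs and incremental cost-effectiveness.

Annual accrual follows the model's accounting conventions: a state
background cost (CAD 2022) plus comorbidity costs — acute events carry an
event-year cost, chronic conditions an annual cost in every year present —
with pre-diabetes comorbidity costs derived from the diabetic-state costs by
condition-specific ratios.  Utility is a baseline age/sex QALY weight minus
a diabetes decrement and condition decrements (event-year decrements for
acute events, persistent history and chronic-condition decrements
thereafter), floored at zero.  Years are whole cycles; the death year is
accounted in full (no half-cycle correction).

Discounting is at a configurable annual rate (default 1.5 %), with cycle 0
undiscounted.  Incremental results are computed pairwise per probabilistic
sensitivity analysis (PSA) iteration under common random numbers, and the
incremental net monetary benefit at willingness-to-pay λ is
``INMB = λ·ΔQALY − ΔCost`` per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import EVENT_ORDER, _EIDX, CohortResult
from .errors import ConfigurationError
from .risk_models import LookupTable

log = logging.getLogger(__name__)

_CHRONIC_COST = ("CHF", "IHD", "BLINDNESS", "RENAL_FAILURE", "ULCER")


@dataclass
class CostTable:
    """Annual costs in CAD 2022.

    ``event_costs[ev]`` is the cost incurred in the year an event occurs;
    ``annual_costs[ev]`` the recurring cost in every subsequent year the
    condition is present (chronic conditions and post-acute maintenance).
    ``ngt_ratios`` scale MI/CHF/stroke costs for patients without diabetes.
    """

    t2dm_annual: float
    ngt_annual: float
    event_costs: Mapping[str, float]
    annual_costs: Mapping[str, float]
    ngt_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"MI": 1.0, "CHF": 1.0, "STROKE": 1.0})
    currency: str = "CAD-2022"
    cad_per_usd_ppp: float = 1.18

    def validate(self) -> None:
        for name, m in (("event_costs", self.event_costs),
                        ("annual_costs", self.annual_costs)):
            for ev, v in m.items():
                if v < 0:
                    raise ConfigurationError(f"{name}[{ev}] must be >= 0")
        if self.t2dm_annual < 0 or self.ngt_annual < 0:
            raise ConfigurationError("state background costs must be >= 0")
        for ev, r in self.ngt_ratios.items():
            if r <= 0:
                raise ConfigurationError(f"ngt_ratios[{ev}] must be > 0")

    def to_dict(self) -> dict:
        return {
            "t2dm_annual": self.t2dm_annual, "ngt_annual": self.ngt_annual,
            "event_costs": dict(self.event_costs),
            "annual_costs": dict(self.annual_costs),
            "ngt_ratios": dict(self.ngt_ratios),
            "currency": self.currency,
            "cad_per_usd_ppp": self.cad_per_usd_ppp,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CostTable":
        try:
            t = cls(
                t2dm_annual=float(d["t2dm_annual"]),
                ngt_annual=float(d.get("ngt_annual", 0.0)),
                event_costs={k: float(v) for k, v in d["event_costs"].items()},
                annual_costs={k: float(v)
                              for k, v in d.get("annual_costs", {}).items()},
                ngt_ratios={k: float(v)
                            for k, v in d.get("ngt_ratios", {}).items()},
                currency=d.get("currency", "CAD-2022"),
                cad_per_usd_ppp=float(d.get("cad_per_usd_ppp", 1.18)),
            )
        except KeyError as e:
            raise ConfigurationError(
                f"cost table: missing required key {e.args[0]!r}") from None
        t.validate()
        return t


@dataclass
class UtilityTable:
    """Baseline QALY weights by age/sex and condition decrements."""

    baseline: LookupTable
    t2dm_decrement: float
    event_decrements: Mapping[str, float]     # event-year, acute events
    history_decrements: Mapping[str, float]   # persistent after occurrence

    def validate(self) -> None:
        for arr in (self.baseline.male, self.baseline.female):
            if np.any((np.asarray(arr) < 0) | (np.asarray(arr) > 1)):
                raise ConfigurationError("baseline utilities must be in [0,1]")
        for m in (self.event_decrements, self.history_decrements):
            for k, v in m.items():
                if v < 0:
                    raise ConfigurationError(f"decrement {k} must be >= 0")
        if self.t2dm_decrement < 0:
            raise ConfigurationError("t2dm_decrement must be >= 0")

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "t2dm_decrement": self.t2dm_decrement,
            "event_decrements": dict(self.event_decrements),
            "history_decrements": dict(self.history_decrements),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "UtilityTable":
        try:
            t = cls(
                baseline=LookupTable.from_dict(d["baseline"],
                                               "baseline utility"),
                t2dm_decrement=float(d.get("t2dm_decrement", 0.0)),
                event_decrements={k: float(v)
                                  for k, v in d["event_decrements"].items()},
                history_decrements={k: float(v) for k, v in
                                    d.get("history_decrements", {}).items()},
            )
        except KeyError as e:
            raise ConfigurationError(
                f"utility table: missing required key {e.args[0]!r}"
            ) from None
        t.validate()
        return t


@dataclass
class CEAResult:
    """Incremental cost-effectiveness summary over PSA iterations."""

    delta_cost: float
    delta_qaly: float
    inmb: float
    wtp: float
    delta_cost_ci: tuple[float, float]
    delta_qaly_ci: tuple[float, float]
    inmb_ci: tuple[float, float]
    per_iteration: pd.DataFrame
    cumulative_inmb_path: np.ndarray | None = None
    first_positive_inmb_year: int | None = None
    event_rate_differences: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "wtp": self.wtp,
            "delta_cost": self.delta_cost, "delta_cost_ci": list(self.delta_cost_ci),
            "delta_qaly": self.delta_qaly, "delta_qaly_ci": list(self.delta_qaly_ci),
            "inmb": self.inmb, "inmb_ci": list(self.inmb_ci),
            "first_positive_inmb_year": self.first_positive_inmb_year,
            "event_rate_differences": self.event_rate_differences,
        }
        if self.cumulative_inmb_path is not None:
            d["cumulative_inmb_path"] = [float(x)
                                         for x in self.cumulative_inmb_path]
        return d


# --------------------------------------------------------------------------
# accrual


def accrue_cohort(result: CohortResult, cost_table: CostTable,
                  utility_table: UtilityTable) -> tuple[np.ndarray, np.ndarray]:
    """Undiscounted (cost, qaly) arrays of shape (horizon, n)."""
    T, n = result.horizon, result.n
    cost = np.zeros((T, n))
    qaly = np.zeros((T, n))
    cum_events = np.zeros((n, len(EVENT_ORDER)), dtype=bool)
    floored = False
    for t in range(T):
        alive = result.alive_start[t]
        if not alive.any():
            break
        t2dm = result.t2dm_start[t]
        ngt = alive & ~t2dm
        ev_t = result.events[t]
        present = cum_events | ev_t          # condition present this year
        c = np.where(t2dm, cost_table.t2dm_annual, cost_table.ngt_annual)
        u = utility_table.baseline.lookup(result.age_start[t], result.female)
        u = u - np.where(t2dm, utility_table.t2dm_decrement, 0.0)
        for ev, e in _EIDX.items():
            ratio = np.where(ngt, cost_table.ngt_ratios.get(ev, 1.0), 1.0)
            ev_cost = cost_table.event_costs.get(ev, 0.0)
            ann_cost = cost_table.annual_costs.get(ev, 0.0)
            if ev_cost:
                c = c + np.where(ev_t[:, e], ev_cost * ratio, 0.0)
            if ann_cost:
                # recurring cost in years after (and including) onset,
                # excluding double-charging the event-year cost
                recur = present[:, e] & ~ev_t[:, e]
                c = c + np.where(recur, ann_cost * ratio, 0.0)
            dec_ev = utility_table.event_decrements.get(ev, 0.0)
            dec_hist = utility_table.history_decrements.get(ev, 0.0)
            if dec_ev:
                u = u - np.where(ev_t[:, e], dec_ev, 0.0)
            if dec_hist:
                u = u - np.where(present[:, e] & ~ev_t[:, e], dec_hist, 0.0)
        if not floored and np.any(alive & (u < 0)):
            log.warning("utility decrements exceeded baseline (first in "
                        "year %d); flooring QALY weight at 0", t)
            floored = True
        cost[t] = np.where(alive, c, 0.0)
        qaly[t] = np.where(alive, np.maximum(u, 0.0), 0.0)
        cum_events |= ev_t
    return cost, qaly


def accrue_year(record, cost_table: CostTable, utility_table: UtilityTable,
                state: str, *, age: float | None = None,
                female: bool = False,
                condition_present: set | frozenset = frozenset()
                ) -> tuple[float, float]:
    """Undiscounted (cost, qaly) for a single annual record.

    ``condition_present`` lists conditions carried from earlier years (their
    annual costs and history decrements apply); the record's own events get
    event-year costs and decrements.
    """
    t2dm = state == "T2DM"
    cost = cost_table.t2dm_annual if t2dm else cost_table.ngt_annual
    a = record.age_at_start if age is None else age
    u = float(utility_table.baseline.lookup(np.array([a]),
                                            np.array([female]))[0])
    if t2dm:
        u -= utility_table.t2dm_decrement
    for ev in record.events:
        ratio = 1.0 if t2dm else cost_table.ngt_ratios.get(ev, 1.0)
        cost += cost_table.event_costs.get(ev, 0.0) * ratio
        u -= utility_table.event_decrements.get(ev, 0.0)
    for ev in set(condition_present) - set(record.events):
        ratio = 1.0 if t2dm else cost_table.ngt_ratios.get(ev, 1.0)
        cost += cost_table.annual_costs.get(ev, 0.0) * ratio
        u -= utility_table.history_decrements.get(ev, 0.0)
    if u < 0:
        log.warning("utility floored at 0 for patient-year %s",
                    record.year_index)
        u = 0.0
    return cost, u


def discount(value, year_index, rate: float = 0.015):
    """Discount a value accrued in cycle ``year_index`` (cycle 0 = 1.0)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return np.asarray(value) / (1.0 + rate) ** np.asarray(year_index)


def discounted_totals(cost: np.ndarray, qaly: np.ndarray,
                      rate: float = 0.015) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient discounted totals from (horizon, n) accrual arrays."""
    T = cost.shape[0]
    w = 1.0 / (1.0 + rate) ** np.arange(T)
    return w @ cost, w @ qaly


# --------------------------------------------------------------------------
# incremental analysis


def incremental_results(control: pd.DataFrame, intervention: pd.DataFrame,
                        wtp: float = 30_000.0,
                        cumulative_paths: tuple[np.ndarray, np.ndarray] | None = None
                        ) -> CEAResult:
    """Pairwise incremental outcomes over matched PSA iterations.

    ``control`` and ``intervention`` must have matching ``iteration`` rows
    with per-patient-mean ``cost`` and ``qaly`` columns.  Percentile (2.5,
    97.5) uncertainty intervals are taken over iterations.
    ``cumulative_paths`` optionally supplies per-year cumulative discounted
    (cost, qaly) difference paths of shape (iterations, horizon) used for
    the cumulative-INMB path and break-even year.
    """
    if len(control) != len(intervention):
        raise ValueError(
            f"mismatched PSA iteration counts: {len(control)} vs "
            f"{len(intervention)}")
    dc = intervention["cost"].to_numpy() - control["cost"].to_numpy()
    dq = intervention["qaly"].to_numpy() - control["qaly"].to_numpy()
    inmb = wtp * dq - dc
    per_iter = pd.DataFrame({
        "iteration": np.arange(len(dc)),
        "delta_cost": dc, "delta_qaly": dq, "inmb": inmb,
    })

    def ci(x):
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    path = None
    first_pos = None
    if cumulative_paths is not None:
        dcost_path, dqaly_path = cumulative_paths
        inmb_path = (wtp * dqaly_path - dcost_path).mean(axis=0)
        path = inmb_path
        pos = np.nonzero(inmb_path > 0)[0]
        first_pos = int(pos[0]) + 1 if len(pos) else None
    return CEAResult(
        delta_cost=float(dc.mean()), delta_qaly=float(dq.mean()),
        inmb=float(inmb.mean()), wtp=wtp,
        delta_cost_ci=ci(dc), delta_qaly_ci=ci(dq), inmb_ci=ci(inmb),
        per_iteration=per_iter,
        cumulative_inmb_path=path, first_positive_inmb_year=first_pos,
    )


def event_rate_per_100k(result_or_trajectories, event: str) -> float:
    """First-occurrence incidence per 100,000 person-years at risk.

    At-risk time counts whole years alive before the first occurrence of
    ``event`` (the occurrence year itself counts as an at-risk year).
    """
    if isinstance(result_or_trajectories, CohortResult):
        res = result_or_trajectories
        first = res.first_event_year(event)
        censor = res.censor_year()
        at_risk = np.where(first > 0, first, censor)
        events = int((first > 0).sum())
        py = float(at_risk.sum())
    else:
        events = 0
        py = 0.0
        for traj in result_or_trajectories:
            yrs = 0
            hit = False
            for rec in traj.records:
                yrs += 1
                if event in rec.events or (
                        event == "death" and rec.died):
                    hit = True
                    break
            events += int(hit)
            py += yrs
    if py <= 0:
        raise ValueError("no person-years at risk")
    return 100_000.0 * events / py
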