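"""Probabilistic sensitivity analysis (PSA).

Parameter uncertainty is handled by drawing complete parameter sets —
equation coefficients, transition parameters, costs and utilities — from
configured prior distributions and re-running the simulation for each draw
against the *same* initial population (the cohort is generated once and is
bit-identical across iterations, so parameter and sampling uncertainty stay
separable).  Prior families follow common conventions in cost-effectiveness
analysis: beta for probabilities, gamma or lognormal for costs and
decrements, normal (optionally jointly multivariate normal) for equation
coefficients.

Each iteration's within-simulation randomness uses a seed derived from the
master seed and the draw id, so any subset of iterations can be reproduced
independently and results do not depend on execution order.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import streams
from .economics import CostTable, UtilityTable, accrue_cohort
from .engine import simulate_cohort
from .errors import ConfigurationError
from .risk_models import CoefficientTable
from .validation import DEFAULT_EVAL_TIMES, km_cumulative_failure

_MAX_RETRIES = 100


@dataclass
class ParameterSet:
    """One complete realisation of all model parameters."""

    coefficients: CoefficientTable
    costs: CostTable
    utilities: UtilityTable
    draw_id: int = 0
    seed: int = 0


def _resolve(d: dict, path: str):
    """Navigate a nested dict by dotted path; returns (container, leaf key)."""
    parts = path.split(".")
    cur = d
    for p in parts[:-1]:
        if not isinstance(cur, dict) or p not in cur:
            raise ConfigurationError(f"prior target {path!r}: key {p!r} "
                                     "not found in the parameter tables")
        cur = cur[p]
    leaf = parts[-1]
    if not isinstance(cur, dict) or leaf not in cur:
        raise ConfigurationError(f"prior target {path!r}: key {leaf!r} "
                                 "not found in the parameter tables")
    return cur, leaf


def _draw_scalar(base: float, prior: Mapping, rng: np.random.Generator) -> float:
    family = prior.get("family")
    if family == "fixed" or family is None:
        return base
    if family == "normal":
        return base + rng.normal(0.0, float(prior["sd"]))
    if family == "lognormal":
        cv = float(prior["cv"])
        sigma = np.sqrt(np.log1p(cv * cv))
        return base * float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
    if family == "gamma":
        cv = float(prior["cv"])
        if base == 0.0:
            return 0.0
        shape = 1.0 / (cv * cv)
        return float(rng.gamma(shape, base / shape))
    if family == "beta":
        strength = float(prior.get("strength", 100.0))
        if not 0.0 < base < 1.0:
            raise ConfigurationError(
                f"beta prior requires a base value in (0,1), got {base}")
        return float(rng.beta(base * strength, (1.0 - base) * strength))
    raise ConfigurationError(f"unknown prior family {family!r}")


def sample_parameter_set(priors: Sequence[Mapping], base: ParameterSet,
                         draw_id: int, master_seed: int) -> ParameterSet:
    """Draw one ParameterSet from the priors around the point estimates.

    Each prior entry addresses a scalar by dotted path into the namespaces
    ``coefficients``, ``costs`` and ``utilities`` (e.g.
    ``coefficients.transition.p_jump`` or ``costs.event_costs.MI``).  An
    entry with a ``targets`` list and a ``cov`` matrix draws the addressed
    coefficients jointly from a multivariate normal centred on the point
    estimates.  Draws violating table invariants are retried a bounded
    number of times.
    """
    seed_key = int(streams.derive_key(master_seed, "psa", draw_id)) % (2 ** 31)
    rng = np.random.default_rng(seed_key)
    base_dicts = {
        "coefficients": base.coefficients.to_dict(),
        "costs": base.costs.to_dict(),
        "utilities": base.utilities.to_dict(),
    }
    for attempt in range(_MAX_RETRIES):
        d = copy.deepcopy(base_dicts)
        try:
            for prior in priors:
                if "targets" in prior:
                    paths = list(prior["targets"])
                    cov = np.asarray(prior["cov"], dtype=float)
                    means = []
                    slots = []
                    for path in paths:
                        cont, leaf = _resolve(d, path)
                        means.append(float(cont[leaf]))
                        slots.append((cont, leaf))
                    draw = rng.multivariate_normal(means, cov)
                    for (cont, leaf), v in zip(slots, draw):
                        cont[leaf] = float(v)
                else:
                    cont, leaf = _resolve(d, prior["target"])
                    cont[leaf] = _draw_scalar(float(cont[leaf]), prior, rng)
            return ParameterSet(
                coefficients=CoefficientTable.from_dict(d["coefficients"]),
                costs=CostTable.from_dict(d["costs"]),
                utilities=UtilityTable.from_dict(d["utilities"]),
                draw_id=draw_id, seed=seed_key,
            )
        except ConfigurationError:
            if attempt == _MAX_RETRIES - 1:
                raise
            continue
    raise ConfigurationError("parameter draws kept violating invariants")


def _program_cost_array(spec, alive_start: np.ndarray,
                        compliant: np.ndarray) -> np.ndarray:
    """(horizon, n) undiscounted programme costs."""
    T, n = alive_start.shape
    out = np.zeros((T, n))
    sched = list(spec.cost_schedule)
    charge = compliant if spec.cost_compliers_only else np.ones(n, dtype=bool)
    for t in range(min(T, len(sched))):
        out[t] = np.where(alive_start[t] & charge, sched[t], 0.0)
    return out


def run_psa(cohort, base: ParameterSet, priors: Sequence[Mapping],
            horizon: int, n_iterations: int, seed: int,
            arms: Mapping[str, Mapping] | None = None,
            discount_rate: float = 0.015,
            endpoints: Sequence[str] = (),
            eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
            share_sim_seed: bool = False,
            progress: bool = False) -> dict:
    """Run the full PSA loop against a fixed cohort.

    ``arms`` maps an arm name to ``{"intervention": InterventionSpec|None,
    "compliant": bool array|None}``; by default a single no-intervention
    arm named ``"base"`` is run.  Within an iteration all arms share the
    same simulation seed (common random numbers).

    Returns a dict per arm with an ``outcomes`` DataFrame (per-iteration
    per-patient-mean discounted cost and QALYs), per-year discounted mean
    accrual paths, KM cumulative-failure samples for each requested
    endpoint, and first-occurrence event rates per 100,000 person-years.
    """
    if arms is None:
        arms = {"base": {"intervention": None, "compliant": None}}
    T = horizon
    disc = 1.0 / (1.0 + discount_rate) ** np.arange(T)
    out: dict = {name: {
        "cost": np.zeros(n_iterations), "qaly": np.zeros(n_iterations),
        "yearly_cost": np.zeros((n_iterations, T)),
        "yearly_qaly": np.zeros((n_iterations, T)),
        "km": {ep: np.zeros((n_iterations, len(eval_times)))
               for ep in endpoints},
        "rates": {ep: np.zeros(n_iterations) for ep in endpoints},
    } for name in arms}

    iters = range(n_iterations)
    if progress:
        try:
            from tqdm import tqdm
            iters = tqdm(iters, desc="PSA")
        except ImportError:
            pass
    for d in iters:
        params = sample_parameter_set(priors, base, d, seed)
        sim_seed = int(streams.derive_key(
            seed, "sim-seed", 0 if share_sim_seed else d)) % (2 ** 31)
        for name, arm in arms.items():
            res = simulate_cohort(
                cohort, params.coefficients, horizon, sim_seed,
                intervention=arm.get("intervention"),
                compliant=arm.get("compliant"),
            )
            cost, qaly = accrue_cohort(res, params.costs, params.utilities)
            if arm.get("intervention") is not None:
                cost = cost + _program_cost_array(
                    arm["intervention"], res.alive_start, arm["compliant"])
            yearly_cost = disc * cost.mean(axis=1)
            yearly_qaly = disc * qaly.mean(axis=1)
            slot = out[name]
            slot["yearly_cost"][d] = yearly_cost
            slot["yearly_qaly"][d] = yearly_qaly
            slot["cost"][d] = yearly_cost.sum()
            slot["qaly"][d] = yearly_qaly.sum()
            for ep in endpoints:
                curve = km_cumulative_failure(res, ep, eval_times)
                slot["km"][ep][d] = curve.cumulative_failure
                first = res.first_event_year(ep)
                censor = res.censor_year()
                at_risk = np.where(first > 0, first, censor)
                py = float(at_risk.sum())
                slot["rates"][ep][d] = (
                    100_000.0 * float((first > 0).sum()) / py if py else 0.0)
    for name in arms:
        slot = out[name]
        slot["outcomes"] = pd.DataFrame({
            "iteration": np.arange(n_iterations),
            "cost": slot["cost"], "qaly": slot["qaly"],
        })
    return out
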