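"""Internal and external validation metrics.

Internal validation compares simulated Kaplan–Meier (KM) cumulative failure
probabilities for each comorbidity and mortality at years 5, 10, 15 and 20
against observed reference values, summarised by an ordinary-least-squares
calibration regression of predicted on observed (intercept, slope, R²; a
perfectly calibrated model gives 0, 1, 1) and the mean absolute difference
in percentage points.  Endpoints can be pooled or restricted to the
microvascular (blindness, renal failure, amputation, diabetic ulcer) or
macrovascular (CHF, IHD, MI, stroke) subsets.

External validation compares simulated to observed annual KM cumulative
incidence of diabetes onset and reports the per-year and average
simulated-to-observed ratio; values near one indicate good alignment.

Events occur on a discrete annual grid, so the KM estimator here is the
product-limit estimator over integer years with deaths (for non-mortality
endpoints) and the horizon treated as censoring; ties between an event and
censoring in the same year count the event first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .engine import CohortResult

DEFAULT_EVAL_TIMES = (5, 10, 15, 20)

MICROVASCULAR = ("BLINDNESS", "RENAL_FAILURE", "AMPUTATION", "ULCER")
MACROVASCULAR = ("CHF", "IHD", "MI", "STROKE")
ALL_ENDPOINTS = MACROVASCULAR + MICROVASCULAR + ("death",)


@dataclass
class KMCurve:
    """Cumulative failure probability over discrete years."""

    times: np.ndarray
    cumulative_failure: np.ndarray
    n_at_risk: np.ndarray
    endpoint: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_failure = np.asarray(self.cumulative_failure,
                                             dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)

    def at(self, time: float) -> float:
        idx = np.searchsorted(self.times, time, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.cumulative_failure[idx])


@dataclass
class CalibrationFit:
    """OLS calibration of predicted on observed values."""

    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    r_squared: float
    mean_absolute_difference: float       # percentage points
    endpoint_subset: str = "all"
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "endpoint_subset": self.endpoint_subset,
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "slope": self.slope, "slope_ci": list(self.slope_ci),
            "r_squared": self.r_squared,
            "mean_absolute_difference_pct": self.mean_absolute_difference,
            "n_points": self.n_points,
        }


def km_from_event_times(event_years: np.ndarray, censor_years: np.ndarray,
                        eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
                        endpoint: str = "") -> KMCurve:
    """Product-limit cumulative failure from discrete first-event times.

    ``event_years[i]`` is the whole-year time of patient *i*'s first event
    (-1 or 0 if none); ``censor_years[i]`` the follow-up end.  A patient
    with an event at the same year as their censoring counts as an event.
    """
    event_years = np.asarray(event_years)
    censor_years = np.asarray(censor_years)
    if len(event_years) == 0:
        raise ValueError("no patients")
    has_event = event_years > 0
    obs_time = np.where(has_event, event_years, censor_years)
    max_t = int(np.max(eval_times))
    surv = 1.0
    out_cf, out_n = [], []
    eval_times = sorted(eval_times)
    truncated = False
    cf_by_year = {}
    n_by_year = {}
    for y in range(1, max_t + 1):
        at_risk = int(np.sum(obs_time >= y))
        d = int(np.sum(has_event & (event_years == y)))
        if at_risk > 0:
            surv *= 1.0 - d / at_risk
        elif not truncated:
            warnings.warn(
                f"no patients at risk at year {y}; KM curve truncated",
                stacklevel=2)
            truncated = True
        cf_by_year[y] = 1.0 - surv
        n_by_year[y] = at_risk
    for tt in eval_times:
        out_cf.append(cf_by_year[int(tt)])
        out_n.append(n_by_year[int(tt)])
    return KMCurve(np.asarray(eval_times, dtype=float),
                   np.asarray(out_cf), np.asarray(out_n), endpoint=endpoint)


def km_cumulative_failure(trajectories, endpoint: str,
                          eval_times: Sequence[float] = DEFAULT_EVAL_TIMES
                          ) -> KMCurve:
    """KM cumulative failure for one endpoint from simulation output.

    ``trajectories`` is a :class:`~t2dsim.engine.CohortResult` or a list of
    :class:`~t2dsim.engine.Trajectory`.  For non-mortality endpoints, death
    censors at the death year; the horizon censors all survivors.
    """
    if isinstance(trajectories, CohortResult):
        first = trajectories.first_event_year(endpoint)
        censor = trajectories.censor_year()
    else:
        if not trajectories:
            raise ValueError("no trajectories")
        first_l, censor_l = [], []
        for traj in trajectories:
            f = -1
            for rec in traj.records:
                hit = (rec.died if endpoint == "death"
                       else endpoint in rec.events)
                if hit:
                    f = rec.year_index + 1
                    break
            first_l.append(f)
            censor_l.append(len(traj.records))
        first = np.asarray(first_l)
        censor = np.asarray(censor_l)
    return km_from_event_times(first, censor, eval_times, endpoint=endpoint)


def calibration_regression(predicted: Sequence[float],
                           observed: Sequence[float],
                           endpoint_subset: str = "all") -> CalibrationFit:
    """OLS of predicted on observed with 95 % t-based confidence intervals."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    n = len(predicted)
    if n < 3:
        raise ValueError("calibration regression needs at least 3 points")
    X = sm.add_constant(observed)
    fit = sm.OLS(predicted, X).fit()
    ci = fit.conf_int(alpha=0.05)
    mad = float(np.mean(np.abs(predicted - observed))) * 100.0
    return CalibrationFit(
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope=float(fit.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(fit.rsquared),
        mean_absolute_difference=mad,
        endpoint_subset=endpoint_subset,
        n_points=n,
    )


def incidence_ratio(simulated: KMCurve, observed: KMCurve
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-year simulated/observed cumulative-incidence ratios and mean.

    Returns (times, ratios, average).  Years with an observed value of zero
    are excluded with a warning.
    """
    common = np.intersect1d(simulated.times, observed.times)
    if len(common) == 0:
        raise ValueError("curves share no evaluation times")
    sim = np.array([simulated.at(t) for t in common])
    obs = np.array([observed.at(t) for t in common])
    ok = obs > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} year(s) with observed incidence 0",
            stacklevel=2)
    if not ok.any():
        raise ValueError("observed incidence is zero at all common times")
    ratios = sim[ok] / obs[ok]
    return common[ok], ratios, float(ratios.mean())


def validation_points(sim_curves: dict, obs_curves: dict,
                      endpoints: Sequence[str],
                      eval_times: Sequence[float] = DEFAULT_EVAL_TIMES
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Paired (predicted, observed) points across endpoints and times."""
    pred, obs = [], []
    for ep in endpoints:
        for tt in eval_times:
            pred.append(sim_curves[ep].at(tt))
            obs.append(obs_curves[ep].at(tt))
    return np.asarray(pred), np.asarray(obs)
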