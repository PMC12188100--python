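"""Synthetic patient populations.

A cohort is a set of simulated individuals whose baseline characteristics
(age, sex, HbA1c, BMI, blood pressure, lipids, renal function, haematology,
comorbidity flags, smoking) are drawn from configured marginal distributions,
optionally coupled through a Gaussian copula.  The initial glycaemic health
state is classified from HbA1c: below 6.5 % the patient is in the combined
normal-glucose-tolerance / pre-diabetes state (``NGT_PRE``); at 6.5 % or
above the patient has type 2 diabetes (``T2DM``).

Patients whose HbA1c lies in the pre-diabetes band are additionally eligible
for the sudden-rise ("jump") transition to diabetes evaluated by the engine.

Sampling is inverse-CDF based on per-patient keyed substreams, so a cohort is
bit-reproducible from its spec and seed, and enlarging a cohort never alters
the patients already drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from . import streams
from .errors import ConfigurationError

NGT_PRE = "NGT_PRE"
T2DM = "T2DM"

T2DM_THRESHOLD = 6.5          # % HbA1c at/above which the patient has T2DM
PRE_T2DM_LOWER = 6.0          # lower edge of the pre-diabetes jump band

#: continuous baseline characteristics, in canonical order
CONTINUOUS_FIELDS = (
    "age", "hba1c", "bmi", "sbp", "ldl", "hdl",
    "egfr", "haem", "wbc", "heart_rate",
)
#: binary baseline characteristics (``female`` encodes sex)
BINARY_FIELDS = ("female", "albuminuria", "pvd", "af", "lvh", "smoker")

ALL_FIELDS = CONTINUOUS_FIELDS + BINARY_FIELDS

_FAMILIES = ("normal", "lognormal", "bernoulli", "categorical", "fixed")


# --------------------------------------------------------------------------
# data model


@dataclass
class RiskFactorVector:
    """One individual's current risk-factor values."""

    hba1c: float
    bmi: float
    sbp: float
    ldl: float
    hdl: float
    egfr: float
    haem: float
    wbc: float
    heart_rate: float
    albuminuria: bool = False
    pvd: bool = False
    af: bool = False
    lvh: bool = False
    smoker: bool = False


@dataclass
class PatientState:
    """One simulated individual at a point in time."""

    patient_id: int
    age: float
    female: bool
    risk_factors: RiskFactorVector
    state: str = NGT_PRE
    years_since_t2dm: int = 0
    alive: bool = True
    history: "object | None" = None  # engine.EventHistory once simulated

    @property
    def sex(self) -> str:
        return "female" if self.female else "male"


@dataclass
class Distribution:
    """Marginal distribution descriptor for one characteristic."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    lower: float | None = None
    upper: float | None = None

    def validate(self, name: str) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"{name}: unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.family == "normal":
            if "mean" not in self.params or "sd" not in self.params:
                raise ConfigurationError(f"{name}: normal needs mean and sd")
            if self.params["sd"] < 0:
                raise ConfigurationError(f"{name}: sd must be >= 0")
        elif self.family == "lognormal":
            if "mu" not in self.params or "sigma" not in self.params:
                raise ConfigurationError(
                    f"{name}: lognormal needs mu and sigma (log scale)"
                )
        elif self.family == "bernoulli":
            p = self.params.get("p")
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}: bernoulli needs p in [0,1]")
        elif self.family == "categorical":
            vals = self.params.get("values")
            probs = self.params.get("probs")
            if not vals or not probs or len(vals) != len(probs):
                raise ConfigurationError(
                    f"{name}: categorical needs matching values/probs"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: categorical probs must sum to 1")
        elif self.family == "fixed":
            if "value" not in self.params:
                raise ConfigurationError(f"{name}: fixed needs value")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ConfigurationError(
                    f"{name}: truncation bounds [{self.lower}, {self.upper}] "
                    "exclude all mass"
                )

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF, with truncation folded into the uniform."""
        if self.family == "fixed":
            return np.full_like(u, float(self.params["value"]))
        if self.family == "bernoulli":
            return (u < float(self.params["p"])).astype(float)
        if self.family == "categorical":
            probs = np.asarray(self.params["probs"], dtype=float)
            vals = np.asarray(self.params["values"], dtype=float)
            idx = np.searchsorted(np.cumsum(probs), u, side="right")
            return vals[np.clip(idx, 0, len(vals) - 1)]
        if self.family == "normal":
            dist = stats.norm(self.params["mean"], self.params["sd"])
        else:  # lognormal
            dist = stats.lognorm(
                s=self.params["sigma"], scale=math.exp(self.params["mu"])
            )
        lo = dist.cdf(self.lower) if self.lower is not None else 0.0
        hi = dist.cdf(self.upper) if self.upper is not None else 1.0
        if hi - lo <= 0.0:
            raise ConfigurationError(
                "truncation bounds exclude all probability mass"
            )
        return dist.ppf(lo + u * (hi - lo))


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``distributions`` maps every baseline field to a descriptor;
    ``correlation`` optionally couples continuous fields through a Gaussian
    copula (rank correlation structure), leaving the configured marginals
    intact.
    """

    distributions: Mapping[str, Distribution]
    n_patients: int
    seed: int
    years_since_t2dm: int = 0
    correlation: tuple[Sequence[str], np.ndarray] | None = None

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        missing = [f for f in ALL_FIELDS if f not in self.distributions]
        if missing:
            raise ConfigurationError(
                f"cohort spec is missing distributions for: {', '.join(missing)}"
            )
        for name, d in self.distributions.items():
            if name not in ALL_FIELDS:
                raise ConfigurationError(f"unknown cohort field {name!r}")
            d.validate(name)
        if self.correlation is not None:
            names, mat = self.correlation
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(names), len(names)):
                raise ConfigurationError("correlation matrix shape mismatch")
            if not np.allclose(mat, mat.T) or np.any(np.diag(mat) != 1.0):
                raise ConfigurationError(
                    "correlation matrix must be symmetric with unit diagonal"
                )


class Cohort:
    """Array-backed cohort; indexable as a sequence of PatientState."""

    def __init__(self, columns: dict[str, np.ndarray],
                 years_since_t2dm: int = 0,
                 patient_ids: np.ndarray | None = None):
        self.columns = columns
        n = len(next(iter(columns.values()))) if columns else 0
        self.n = n
        self.patient_ids = (np.arange(n) if patient_ids is None
                            else np.asarray(patient_ids, dtype=int))
        self.state = np.where(
            columns["hba1c"] >= T2DM_THRESHOLD, T2DM, NGT_PRE
        ) if n else np.array([], dtype=object)
        self.years_since_t2dm = np.where(
            self.state == T2DM, years_since_t2dm, 0
        ).astype(int) if n else np.array([], dtype=int)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> PatientState:
        c = self.columns
        rf = RiskFactorVector(
            hba1c=float(c["hba1c"][i]), bmi=float(c["bmi"][i]),
            sbp=float(c["sbp"][i]), ldl=float(c["ldl"][i]),
            hdl=float(c["hdl"][i]), egfr=float(c["egfr"][i]),
            haem=float(c["haem"][i]), wbc=float(c["wbc"][i]),
            heart_rate=float(c["heart_rate"][i]),
            albuminuria=bool(c["albuminuria"][i]), pvd=bool(c["pvd"][i]),
            af=bool(c["af"][i]), lvh=bool(c["lvh"][i]),
            smoker=bool(c["smoker"][i]),
        )
        return PatientState(
            patient_id=int(self.patient_ids[i]), age=float(c["age"][i]),
            female=bool(c["female"][i]), risk_factors=rf,
            state=str(self.state[i]),
            years_since_t2dm=int(self.years_since_t2dm[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(self.n))

    def subset(self, idx) -> "Cohort":
        out = Cohort.__new__(Cohort)
        out.columns = {k: v[idx] for k, v in self.columns.items()}
        out.n = len(out.columns["age"])
        out.state = self.state[idx]
        out.years_since_t2dm = self.years_since_t2dm[idx]
        out.patient_ids = self.patient_ids[idx]
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_ids})
        for f in ALL_FIELDS:
            col = self.columns[f]
            df[f] = col.astype(bool) if f in BINARY_FIELDS else col
        df["state"] = self.state
        df["years_since_t2dm"] = self.years_since_t2dm
        return df

    @classmethod
    def from_patients(cls, patients: Sequence[PatientState]) -> "Cohort":
        cols: dict[str, list] = {f: [] for f in ALL_FIELDS}
        for p in patients:
            cols["age"].append(p.age)
            cols["female"].append(p.female)
            for f in CONTINUOUS_FIELDS[1:]:
                cols[f].append(getattr(p.risk_factors, f))
            for f in BINARY_FIELDS[1:]:
                cols[f].append(getattr(p.risk_factors, f))
        columns = {
            f: np.asarray(v, dtype=float) for f, v in cols.items()
        }
        ids = np.array([p.patient_id for p in patients], dtype=int)
        out = (cls(columns, patient_ids=ids) if patients
               else cls({f: np.array([]) for f in ALL_FIELDS}))
        # honour explicitly-set states/durations (e.g. absorbing T2DM)
        if patients:
            out.state = np.array([p.state for p in patients], dtype=object)
            out.years_since_t2dm = np.array(
                [p.years_since_t2dm for p in patients], dtype=int
            )
        return out


# --------------------------------------------------------------------------
# operations


def classify_state(hba1c: float) -> str:
    """Glycaemic health state from HbA1c (%): >= 6.5 is T2DM."""
    if not np.isfinite(hba1c):
        raise ValueError(f"hba1c must be finite, got {hba1c}")
    return T2DM if hba1c >= T2DM_THRESHOLD else NGT_PRE


def in_pre_t2dm_band(hba1c, *, include_gap: bool = True):
    """Is HbA1c in the pre-diabetes band eligible for the jump transition?

    The band is nominally 6.0-6.4 %; with ``include_gap`` (default) it is
    treated as [6.0, 6.5) so that no HbA1c value between the band and the
    diabetes threshold falls in an undefined gap.  With
    ``include_gap=False`` the strict band [6.0, 6.4] is used.
    """
    arr = np.asarray(hba1c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("hba1c must be finite")
    upper = T2DM_THRESHOLD if include_gap else 6.4
    res = (arr >= PRE_T2DM_LOWER) & (
        (arr < upper) if include_gap else (arr <= upper)
    )
    return bool(res) if np.isscalar(hba1c) else res


def sample_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from a :class:`CohortSpec`.

    Each patient has an independent keyed substream; characteristic ``j`` of
    patient ``i`` consumes the uniform addressed by (seed, i, j), so the
    cohort is reproducible and extension-stable.
    """
    spec.validate()
    n = spec.n_patients
    keys = streams.patient_keys(spec.seed, "cohort", n)
    columns: dict[str, np.ndarray] = {}

    corr_names: list[str] = []
    chol = None
    if spec.correlation is not None:
        corr_names = list(spec.correlation[0])
        mat = np.asarray(spec.correlation[1], dtype=float)
        try:
            chol = np.linalg.cholesky(mat)
        except np.linalg.LinAlgError as e:
            raise ConfigurationError(
                "correlation matrix is not positive definite"
            ) from e
        # independent standard normals per correlated field, then couple
        z = np.column_stack(
            [ndtri(np.clip(streams.uniforms(keys, 100, j), 1e-12, 1 - 1e-12))
             for j in range(len(corr_names))]
        ) if n else np.zeros((0, len(corr_names)))
        z = z @ chol.T
        u_corr = {name: ndtr(z[:, j]) for j, name in enumerate(corr_names)}

    for j, name in enumerate(ALL_FIELDS):
        dist = spec.distributions[name]
        if chol is not None and name in corr_names:
            u = np.clip(u_corr[name], 1e-12, 1 - 1e-12)
        else:
            u = streams.uniforms(keys, 0, j) if n else np.array([])
        columns[name] = dist.ppf(u) if n else np.array([])

    return Cohort(columns, years_since_t2dm=spec.years_since_t2dm)


def cohort_spec_from_dict(d: Mapping, *, n_patients=None, seed=None) -> CohortSpec:
    """Build a CohortSpec from a parsed config mapping."""
    dists = {}
    raw = d.get("distributions")
    if raw is None:
        raise ConfigurationError("cohort config requires a 'distributions' block")
    for name, block in raw.items():
        if "family" not in block:
            raise ConfigurationError(f"distribution {name!r} missing 'family'")
        params = {k: v for k, v in block.items()
                  if k not in ("family", "lower", "upper")}
        dists[name] = Distribution(
            family=block["family"], params=params,
            lower=block.get("lower"), upper=block.get("upper"),
        )
    corr = None
    if "correlation" in d and d["correlation"]:
        corr = (list(d["correlation"]["fields"]),
                np.asarray(d["correlation"]["matrix"], dtype=float))
    return CohortSpec(
        distributions=dists,
        n_patients=int(n_patients if n_patients is not None else d["n_patients"]),
        seed=int(seed if seed is not None else d["seed"]),
        years_since_t2dm=int(d.get("years_since_t2dm", 0)),
        correlation=corr,
    )
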