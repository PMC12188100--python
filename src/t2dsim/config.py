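"""Configuration loading, validation and run manifests.

The whole model is parameterised from one structured YAML document (the
packaged ``data/default_model.yaml`` by default): equation tables, the
pre-diabetes transition parameters, cost and utility tables, the
intervention profile, PSA priors, cohort baseline distributions and run
settings.  Loading validates the schema, checks that the required event and
mortality equations are present, and resolves every equation predictor
against the patient-context vocabulary so that a misspelt predictor fails
at load time with the offending equation named.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from .cohort import (
    Cohort, CohortSpec, cohort_spec_from_dict, sample_cohort,
)
from .economics import CostTable, UtilityTable
from .errors import ConfigurationError
from .intervention import InterventionSpec
from .psa import ParameterSet
from .risk_models import CoefficientTable, T2DM_EVENTS

#: every name an equation predictor may refer to
KNOWN_PREDICTORS = frozenset(
    ("age", "female", "male", "duration", "hba1c", "bmi", "sbp", "ldl",
     "hdl", "egfr", "haem", "wbc", "heart_rate", "albuminuria", "pvd",
     "af", "lvh", "smoker")
    + tuple(f"hist_{ev.lower()}" for ev in T2DM_EVENTS)
    + tuple(f"event_{ev.lower()}" for ev in T2DM_EVENTS)
)

FIXTURE_KINDS = ("uk_t2dm_like", "dppos_like", "toy")


@dataclass
class RunSettings:
    horizon: int = 20
    n_patients: int = 5100
    psa_iterations: int = 1000
    discount_rate: float = 0.015
    wtp: float = 30_000.0
    seed: int = 1

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon, "n_patients": self.n_patients,
            "psa_iterations": self.psa_iterations,
            "discount_rate": self.discount_rate, "wtp": self.wtp,
            "seed": self.seed,
        }


@dataclass
class ModelConfig:
    """Validated bundle of everything one run needs."""

    run: RunSettings
    coefficients: CoefficientTable
    costs: CostTable
    utilities: UtilityTable
    intervention: InterventionSpec
    priors: list = field(default_factory=list)
    cohorts: dict = field(default_factory=dict)

    def base_parameter_set(self) -> ParameterSet:
        """Point-estimate ParameterSet (PSA draw 0 equivalent)."""
        return ParameterSet(coefficients=self.coefficients, costs=self.costs,
                            utilities=self.utilities, draw_id=-1, seed=0)

    def cohort_spec(self, kind: str, n: int | None = None,
                    seed: int | None = None) -> CohortSpec:
        if kind not in self.cohorts:
            raise ConfigurationError(
                f"unknown cohort kind {kind!r}; available: "
                f"{sorted(self.cohorts)}")
        block = dict(self.cohorts[kind])
        block.setdefault("n_patients", self.run.n_patients)
        block.setdefault("seed", self.run.seed)
        return cohort_spec_from_dict(block, n_patients=n, seed=seed)

    def to_dict(self) -> dict:
        return {
            "run": self.run.to_dict(),
            "coefficients": self.coefficients.to_dict(),
            "costs": self.costs.to_dict(),
            "utilities": self.utilities.to_dict(),
            "intervention": self.intervention.to_dict(),
            "priors": list(self.priors),
            "cohorts": self.cohorts,
        }


def _check_predictors(table: CoefficientTable) -> None:
    for eq in table._all_equations():
        for pred in eq.coefficients:
            if pred != "intercept" and pred not in KNOWN_PREDICTORS:
                raise ConfigurationError(
                    f"equation {eq.name!r}: predictor {pred!r} does not "
                    "resolve to a patient-state field or derived quantity")


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a model configuration.

    With no ``path`` the packaged default parameterisation is used.
    """
    if path is None:
        ref = importlib.resources.files("t2dsim.data") / "default_model.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    for block in ("coefficients", "costs", "utilities"):
        if block not in raw:
            raise ConfigurationError(f"missing config block {block!r}")
    run_raw = raw.get("run", {})
    run = RunSettings(
        horizon=int(run_raw.get("horizon", 20)),
        n_patients=int(run_raw.get("n_patients", 5100)),
        psa_iterations=int(run_raw.get("psa_iterations", 1000)),
        discount_rate=float(run_raw.get("discount_rate", 0.015)),
        wtp=float(run_raw.get("wtp", 30_000.0)),
        seed=int(run_raw.get("seed", 1)),
    )
    table = CoefficientTable.from_dict(raw["coefficients"])
    _check_predictors(table)
    cfg = ModelConfig(
        run=run,
        coefficients=table,
        costs=CostTable.from_dict(raw["costs"]),
        utilities=UtilityTable.from_dict(raw["utilities"]),
        intervention=InterventionSpec.from_dict(raw.get("intervention", {})),
        priors=list(raw.get("priors", [])),
        cohorts=dict(raw.get("cohorts", {})),
    )
    # validate cohort blocks eagerly so errors surface at load time
    for kind in cfg.cohorts:
        cfg.cohort_spec(kind, n=1, seed=0).validate()
    return cfg


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Serialise a configuration; ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def config_hash(cfg: ModelConfig) -> str:
    """Stable hash of the semantic content of a configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_fixture_cohort(kind: str, n: int, seed: int,
                        cfg: ModelConfig | None = None
                        ) -> tuple[Cohort, CohortSpec]:
    """Generate one of the packaged study cohorts.

    ``uk_t2dm_like`` draws a newly diagnosed diabetic cohort (all patients
    classify T2DM at baseline); ``dppos_like`` a prediabetic prevention
    trial cohort (all classify NGT/pre-T2DM); ``toy`` a small deterministic
    mixed cohort for tests.
    """
    if kind not in FIXTURE_KINDS:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    if cfg is None:
        cfg = load_config()
    spec = cfg.cohort_spec(kind, n=n, seed=seed)
    return sample_cohort(spec), spec


def observed_dppos_curves() -> pd.DataFrame:
    """Packaged synthetic observed diabetes-incidence reference curves."""
    ref = (importlib.resources.files("t2dsim.data")
           / "observed_dppos_t2dm_synthetic.csv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")


@dataclass
class RunManifest:
    """Reproducibility record written next to run outputs."""

    config_hash: str
    master_seed: int
    package_version: str
    timestamp: str
    outputs: list = field(default_factory=list)

    @classmethod
    def create(cls, cfg: ModelConfig, seed: int) -> "RunManifest":
        from . import __version__
        return cls(config_hash=config_hash(cfg), master_seed=seed,
                   package_version=__version__,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def export_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """One row per patient, one column per baseline field."""
    cohort.to_frame().to_csv(path, index=False)


def export_trajectories_csv(trajectories, path: str | Path) -> None:
    """Long-format per-patient-year trajectory export."""
    rows = []
    for traj in trajectories:
        for rec in traj.records:
            row = {
                "patient_id": traj.patient_id, "year": rec.year_index,
                "state": rec.state_at_start,
                "events": ";".join(sorted(rec.events)),
                "died": rec.died,
                "cost_cad2022": rec.undiscounted_cost,
                "qaly": rec.undiscounted_qaly,
            }
            rf = rec.risk_factors_end
            for f in ("hba1c", "bmi", "sbp", "ldl", "hdl", "egfr", "haem",
                      "wbc", "heart_rate"):
                row[f] = getattr(rf, f)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
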