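"""Prevention-programme overlay.

Models a lifestyle-intervention prevention programme in the style of the
Diabetes Prevention Program's intensive lifestyle intervention: per-year
additive shifts to the BMI and HbA1c update outputs over the programme
duration, a multiplicative reduction of the pre-diabetes sudden-rise
("jump") probability, a compliance rate (default 50 %), and a per-year
programme cost schedule.

Effects apply to compliant patients who have not yet developed diabetes;
the post-onset equations are never modified directly — intervention
benefits after onset flow only through the altered risk-factor paths.
By default every intervention-arm patient incurs the programme cost while
only compliers receive effects (intention-to-treat costing); set
``cost_compliers_only`` to charge compliers alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import streams
from .errors import ConfigurationError


@dataclass
class InterventionSpec:
    """Effect and cost profile of a prevention programme.

    ``bmi_shifts`` and ``hba1c_shifts`` are additive adjustments applied to
    the end-of-year update output in programme years 1..duration (index 0 is
    year 1).  ``jump_multiplier`` scales the pre-diabetes jump probability.
    ``cost_schedule`` is the per-enrolled-patient programme cost (CAD) per
    programme year.
    """

    bmi_shifts: Sequence[float] = ()
    hba1c_shifts: Sequence[float] = ()
    jump_multiplier: float = 1.0
    compliance_rate: float = 0.50
    cost_schedule: Sequence[float] = ()
    duration: int = 10
    cost_compliers_only: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.jump_multiplier <= 1.0:
            raise ConfigurationError("jump_multiplier must be in [0, 1]")
        if not 0.0 <= self.compliance_rate <= 1.0:
            raise ConfigurationError("compliance_rate must be in [0, 1]")
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")

    def effect_at(self, year_index: int) -> tuple[float, float]:
        """(BMI shift, HbA1c shift) for cycle ``year_index`` (0-based)."""
        if year_index >= self.duration or year_index < 0:
            return 0.0, 0.0
        b = (self.bmi_shifts[year_index]
             if year_index < len(self.bmi_shifts) else 0.0)
        h = (self.hba1c_shifts[year_index]
             if year_index < len(self.hba1c_shifts) else 0.0)
        return float(b), float(h)

    @classmethod
    def null(cls) -> "InterventionSpec":
        """No effects, no cost: intervention arm identical to standard care."""
        return cls(jump_multiplier=1.0, cost_schedule=(), duration=0)

    def to_dict(self) -> dict:
        return {
            "bmi_shifts": list(map(float, self.bmi_shifts)),
            "hba1c_shifts": list(map(float, self.hba1c_shifts)),
            "jump_multiplier": self.jump_multiplier,
            "compliance_rate": self.compliance_rate,
            "cost_schedule": list(map(float, self.cost_schedule)),
            "duration": self.duration,
            "cost_compliers_only": self.cost_compliers_only,
        }

    @classmethod
    def from_dict(cls, d) -> "InterventionSpec":
        spec = cls(
            bmi_shifts=list(d.get("bmi_shifts", [])),
            hba1c_shifts=list(d.get("hba1c_shifts", [])),
            jump_multiplier=float(d.get("jump_multiplier", 1.0)),
            compliance_rate=float(d.get("compliance_rate", 0.5)),
            cost_schedule=list(d.get("cost_schedule", [])),
            duration=int(d.get("duration", 10)),
            cost_compliers_only=bool(d.get("cost_compliers_only", False)),
        )
        spec.validate()
        return spec


def assign_compliance(cohort, rate: float, seed: int) -> np.ndarray:
    """Independent Bernoulli(rate) compliance flag per patient.

    Keyed by patient id so the assignment is reproducible and independent of
    cohort ordering.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("compliance rate must be in [0, 1]")
    n = len(cohort)
    ids = getattr(cohort, "patient_ids", np.arange(n))
    keys = streams.keys_for_ids(seed, "compliance", np.asarray(ids))
    return streams.uniforms(keys, 0, 0, 0) < rate


def apply_intervention(year_index: int, spec: InterventionSpec,
                       compliant: bool, p_jump: float,
                       bmi_update: float, hba1c_update: float
                       ) -> tuple[float, float, float]:
    """Modified (p_jump, BMI update, HbA1c update) for one patient-year.

    Non-compliant patients and years beyond the programme duration pass
    through unchanged.
    """
    if not compliant or year_index >= spec.duration:
        return p_jump, bmi_update, hba1c_update
    db, dh = spec.effect_at(year_index)
    return (p_jump * spec.jump_multiplier, bmi_update + db, hba1c_update + dh)


def program_cost(year_index: int, spec: InterventionSpec,
                 compliant: bool) -> float:
    """Programme cost charged for one enrolled patient-year (undiscounted)."""
    if spec.cost_compliers_only and not compliant:
        return 0.0
    if year_index < 0 or year_index >= len(spec.cost_schedule):
        return 0.0
    return float(spec.cost_schedule[year_index])
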