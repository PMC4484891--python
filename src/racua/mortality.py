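"""HAQ-adjusted background mortality.

General-population annual death probabilities (life table, by age and
sex) are converted to hazards, multiplied by a relative risk of
rr_per_haq_unit^HAQ (log-linear in disability, base RR 1.330 per HAQ
unit), and converted to per-cycle probabilities.  The RR acts on the
hazard scale, never the probability scale, so adjusted probabilities
stay in [0, 1] at any age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import MortalityInputs
from .synthetic import LifeTable, MAX_AGE

__all__ = [
    "MortalityContext",
    "haq_mortality_multiplier",
    "annual_to_cycle_probability",
    "cycle_death_probability",
]


@dataclass(frozen=True)
class MortalityContext:
    current_mean_age: float
    proportion_female: float
    current_haq: float
    cycle_length_months: float

    def __post_init__(self) -> None:
        if not (18.0 <= self.current_mean_age <= 100.0):
            raise ValueError(f"age {self.current_mean_age} outside [18, 100]")
        if not (0.0 <= self.current_haq <= 3.0):
            raise ValueError(f"HAQ {self.current_haq} outside [0, 3]")
        if not (0.0 <= self.proportion_female <= 1.0):
            raise ValueError("proportion_female must be in [0, 1]")


def haq_mortality_multiplier(haq: float, rr_per_unit: float) -> float:
    """Hazard multiplier rr_per_unit**haq for current disability level."""
    if not (0.0 <= haq <= 3.0):
        raise ValueError(f"HAQ {haq} outside [0, 3]")
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be positive")
    return rr_per_unit ** haq


def annual_to_cycle_probability(p_annual: float, months: float) -> float:
    """Constant-hazard rescaling: 1 − (1 − p)^(months/12).  p = 1 is absorbing."""
    if months <= 0:
        raise ValueError("months must be positive")
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError("p_annual must be in [0, 1]")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (months / 12.0)


def cycle_death_probability(ctx: MortalityContext, m: MortalityInputs,
                            life_table: LifeTable) -> float:
    """Per-cycle death probability at the cohort's current age/sex mix and HAQ.

    The sex-mix-weighted annual probability at the nearest integer age is
    converted to a hazard, scaled by the HAQ multiplier, and converted to
    a probability over the cycle length.  With ``m.enabled`` false the
    unadjusted (RR = 1) value is returned.
    """
    age = int(round(ctx.current_mean_age))
    if age > MAX_AGE:
        raise ValueError(f"age {age} beyond life-table range")
    qx = (ctx.proportion_female * life_table.annual_probability(age, "female")
          + (1.0 - ctx.proportion_female) * life_table.annual_probability(age, "male"))
    if qx >= 1.0:
        return 1.0
    hazard = -math.log1p(-qx)
    if m.enabled:
        hazard *= haq_mortality_multiplier(ctx.current_haq, m.rr_per_haq_unit)
    return min(1.0, 1.0 - math.exp(-hazard * ctx.cycle_length_months / 12.0))


def cycle_death_probabilities(age: float, proportion_female: float,
                              haq_by_state: np.ndarray, cycle_months: float,
                              m: MortalityInputs, life_table: LifeTable) -> np.ndarray:
    """Vectorised ``cycle_death_probability`` over a per-state HAQ array."""
    a = int(round(age))
    if a > MAX_AGE:
        raise ValueError(f"age {a} beyond life-table range")
    qx = (proportion_female * life_table.qx_female[a]
          + (1.0 - proportion_female) * life_table.qx_male[a])
    if qx >= 1.0:
        return np.ones_like(haq_by_state)
    hazard = -math.log1p(-qx)
    if m.enabled:
        hazard = hazard * np.power(m.rr_per_haq_unit, np.clip(haq_by_state, 0.0, 3.0))
    else:
        hazard = np.full_like(haq_by_state, hazard)
    return np.minimum(1.0, 1.0 - np.exp(-hazard * cycle_months / 12.0))
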