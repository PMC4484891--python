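"""Utility (EQ-5D) and HAQ trajectories, and discounted QALY integration.

The health-effect machinery: response-category utility gains over the
first cycle (front-loaded, 80% achieved by week 4 in the base case),
continued small improvement over months 6–18 on treatment, rebound on
discontinuation, HAQ-mapped decline on follow-up therapy, and the
HAQ → EQ-5D mapping ΔEQ-5D = −0.2102·ΔHAQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelSettings, UtilityInputs

__all__ = [
    "haq_to_utility_delta",
    "response_gain",
    "first_cycle_utility_profile",
    "continuation_improvement",
    "rebound_utility_change",
    "offtreatment_haq_drift",
    "discounted_qalys",
    "FirstCycleProfile",
]

WEEKS_PER_YEAR = 52.0
WEEKS_PER_MONTH = 52.0 / 12.0

RESPONSE_CATEGORIES = ("none", "acr20", "acr50", "acr70")


def haq_to_utility_delta(delta_haq: float, coefficient: float = -0.2102) -> float:
    """Map a HAQ-DI change to an EQ-5D utility change (negative slope:
    worsening disability lowers utility)."""
    if abs(delta_haq) > 3.0:
        raise ValueError(f"|delta_haq| must be <= 3, got {delta_haq}")
    return coefficient * delta_haq


def response_gain(category: str, u: UtilityInputs,
                  haq_change_by_category: dict[str, float]) -> float:
    """First-cycle utility gain for an ACR response category.

    Explicit regression-derived gains (``u.response_gain_override``) take
    precedence; otherwise the category's HAQ change is mapped through the
    HAQ → utility coefficient.
    """
    if category not in RESPONSE_CATEGORIES:
        raise ValueError(f"unknown response category {category!r}")
    if u.response_gain_override is not None:
        return float(u.response_gain_override[category])
    return haq_to_utility_delta(haq_change_by_category[category], u.bansback_coefficient)


@dataclass(frozen=True)
class FirstCycleProfile:
    """Piecewise-linear utility over the first treatment cycle.

    Rises from baseline to baseline + front_load_fraction·gain at
    ``front_load_week``, then linearly to baseline + gain at cycle end.
    """

    baseline: float
    gain: float
    front_load_fraction: float
    front_load_week: float
    cycle_weeks: float

    def __call__(self, week: float) -> float:
        w = np.clip(week, 0.0, self.cycle_weeks)
        u_mid = self.baseline + self.front_load_fraction * self.gain
        u_end = self.baseline + self.gain
        if self.front_load_week <= 0 or self.front_load_week >= self.cycle_weeks:
            return float(self.baseline + self.gain * w / self.cycle_weeks)
        if w <= self.front_load_week:
            return float(self.baseline + (u_mid - self.baseline) * w / self.front_load_week)
        return float(u_mid + (u_end - u_mid) * (w - self.front_load_week)
                     / (self.cycle_weeks - self.front_load_week))

    def integral_years(self) -> float:
        """Exact undiscounted QALYs accrued over the cycle (trapezoids)."""
        w1 = min(max(self.front_load_week, 0.0), self.cycle_weeks)
        u0, u1, u2 = self(0.0), self(w1), self(self.cycle_weeks)
        area_weeks = 0.5 * (u0 + u1) * w1 + 0.5 * (u1 + u2) * (self.cycle_weeks - w1)
        return area_weeks / WEEKS_PER_YEAR


def first_cycle_utility_profile(baseline_u: float, gain: float, cycle_months: float,
                                u: UtilityInputs) -> FirstCycleProfile:
    """Build the first-cycle profile, clamping gains that would push utility
    above the ceiling (with a warning)."""
    if baseline_u + gain > u.utility_ceiling:
        warnings.warn(
            f"first-cycle gain {gain:.4f} clamped: baseline {baseline_u:.3f} + gain "
            f"exceeds the utility ceiling {u.utility_ceiling}", stacklevel=2)
        gain = u.utility_ceiling - baseline_u
    return FirstCycleProfile(
        baseline=baseline_u,
        gain=gain,
        front_load_fraction=u.front_load_fraction,
        front_load_week=u.front_load_week,
        cycle_weeks=cycle_months * WEEKS_PER_MONTH,
    )


def continuation_improvement(gain_first_cycle: float, u: UtilityInputs) -> float:
    """Additional utility gained over months 6–18 on continued treatment
    (a small fraction of the first-cycle gain, accrued linearly)."""
    return u.continuation_gain_fraction * gain_first_cycle


def rebound_utility_change(total_on_treatment_gain: float,
                           rebound_fraction: float) -> float:
    """Utility change applied at discontinuation: loss of the configured
    fraction of the accumulated on-treatment gain (100% = back to the
    pre-treatment trajectory)."""
    if not (0.0 <= rebound_fraction <= 1.0):
        raise ValueError("rebound_fraction must be in [0, 1]")
    return -rebound_fraction * total_on_treatment_gain


def offtreatment_haq_drift(haq_now: float, annual_rate: float, months: float,
                           haq_max: float = 3.0) -> float:
    """HAQ worsening while on conventional or palliative therapy, capped at
    the instrument ceiling."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0 for off-biologic states")
    return min(haq_max, haq_now + annual_rate * months / 12.0)


def discounted_qalys(utility_by_cycle: np.ndarray, occupancy: np.ndarray,
                     cycle_start_years: np.ndarray, cycle_length_years: np.ndarray,
                     rate: float, settings: ModelSettings | None = None,
                     half_cycle_correction: bool | None = None) -> float:
    """Discounted QALY total over a trace.

    ``utility_by_cycle`` and ``occupancy`` are (n_cycles, n_states) arrays
    sharing a cycle grid; the death state must carry utility 0.
    Discounting uses the cycle start time, or the midpoint when the
    half-cycle correction is enabled.
    """
    utility_by_cycle = np.asarray(utility_by_cycle, float)
    occupancy = np.asarray(occupancy, float)
    if utility_by_cycle.shape != occupancy.shape:
        raise ValueError("utility and occupancy grids do not match")
    if len(cycle_start_years) != utility_by_cycle.shape[0]:
        raise ValueError("cycle grid length mismatch")
    hcc = (half_cycle_correction if half_cycle_correction is not None
           else bool(settings.half_cycle_correction) if settings is not None else False)
    t = np.asarray(cycle_start_years, float)
    dt = np.asarray(cycle_length_years, float)
    if hcc:
        t = t + dt / 2.0
    disc = (1.0 + rate) ** (-t)
    per_cycle = (occupancy * utility_by_cycle).sum(axis=1) * dt * disc
    return float(per_cycle.sum())


def trajectory_frame(cycle_start_years: np.ndarray, state_names: list[str],
                     haq: np.ndarray, utility: np.ndarray) -> pd.DataFrame:
    """Tidy (cycle, state, mean_haq, mean_utility) export of a trajectory."""
    n_cycles, n_states = haq.shape
    return pd.DataFrame({
        "cycle": np.repeat(np.arange(n_cycles), n_states),
        "time_years": np.repeat(cycle_start_years, n_states),
        "state": state_names * n_cycles,
        "mean_haq": haq.ravel(),
        "mean_utility": utility.ravel(),
    })
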