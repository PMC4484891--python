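"""Per-cycle cost machinery: drug acquisition with dosing schedules and
vial/unit wastage, IV administration, monitoring, HAQ-band resource
costs, inflation and discounting.

Base-case costing is per unit dispensed (unused drug in an opened vial
or syringe is wasted); the per-mg alternative prices the exact dose.
Weight-based drugs either use the fixed cohort weight or integrate the
vial count over the weight distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import (CostingMethod, CostInputs, ModelSettings, Regimen,
                     TreatmentStrategy)
from .synthetic import WeightCDF

__all__ = [
    "DoseEvent",
    "doses_in_window",
    "weight_based_dose",
    "units_dispensed",
    "expected_units_weight_cdf",
    "cycle_drug_cost",
    "administration_and_monitoring_cost",
    "inflate_then_discount",
    "accumulate_costs",
    "haq_band_cost_per_year",
]

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class DoseEvent:
    week: float
    amount: float          # mg, or mg/kg for weight-based regimens
    weight_based: bool


def doses_in_window(regimen: Regimen, start_week: float, end_week: float) -> list[DoseEvent]:
    """Dose events scheduled in the half-open window [start_week, end_week)."""
    if start_week >= end_week:
        return []
    wb = regimen.weight_based
    events = [DoseEvent(w, d, wb) for w, d in regimen.loading_doses
              if start_week <= w < end_week]
    amount = regimen.mg_per_kg if wb else regimen.maintenance_dose_mg
    k = max(0, math.ceil((start_week - regimen.maintenance_start_week)
                         / regimen.maintenance_interval_weeks - 1e-9))
    w = regimen.maintenance_start_week + k * regimen.maintenance_interval_weeks
    while w < end_week - 1e-9:
        if w >= start_week - 1e-9:
            events.append(DoseEvent(w, amount, wb))
        w += regimen.maintenance_interval_weeks
    return sorted(events, key=lambda e: e.week)


def weight_based_dose(mg_per_kg: float, weight_kg: float) -> float:
    if mg_per_kg <= 0 or weight_kg <= 0:
        raise ValueError("dose rate and weight must be positive")
    return mg_per_kg * weight_kg


def units_dispensed(dose_mg: float, unit_strength_mg: float,
                    method: CostingMethod | str) -> float:
    """Units needed for a dose: ceiling under per-unit costing (wastage),
    exact fraction under per-mg costing."""
    if unit_strength_mg <= 0:
        raise ValueError("unit strength must be positive")
    ratio = dose_mg / unit_strength_mg
    if CostingMethod(method) is CostingMethod.per_unit:
        return float(math.ceil(ratio - 1e-9))
    return float(ratio)


def expected_units_weight_cdf(mg_per_kg: float, unit_strength_mg: float,
                              weight_cdf: WeightCDF, max_units: int = 20) -> float:
    """Expected vials per dose under the weight distribution: sum over vial
    counts of the probability mass needing that count.

    A patient needs k vials when weight is in ((k−1)·S/r, k·S/r] with
    S the vial strength and r the mg/kg rate.
    """
    thresholds = np.arange(0, max_units + 1) * unit_strength_mg / mg_per_kg
    cdf_vals = weight_cdf.cdf(thresholds)
    masses = np.diff(cdf_vals)
    masses[-1] += 1.0 - cdf_vals[-1]  # tail mass lumped into the top count
    return float((np.arange(1, max_units + 1) * masses).sum())


def cycle_drug_cost(strategy: TreatmentStrategy, start_week: float, end_week: float,
                    costs: CostInputs, settings: ModelSettings,
                    fixed_weight_kg: float | None = 81.4,
                    weight_cdf: WeightCDF | None = None) -> float:
    """Acquisition cost of the strategy's drug over a cycle window (€,
    undiscounted, cost-year prices).

    Weight-based regimens use the fixed cohort weight, or — when a weight
    distribution is supplied instead — the expected unit count over that
    distribution.  Methotrexate co-therapy is costed at zero in the base
    case (``mtx_cost_zero``).
    """
    if strategy.drug not in costs.drug_unit_costs:
        raise KeyError(f"no unit cost for drug {strategy.drug!r}")
    unit = costs.drug_unit_costs[strategy.drug]
    method = settings.costing_method
    total = 0.0
    for ev in doses_in_window(strategy.regimen, start_week, end_week):
        if ev.weight_based:
            if weight_cdf is not None and method is CostingMethod.per_unit:
                n_units = expected_units_weight_cdf(ev.amount, unit.strength_mg, weight_cdf)
            else:
                if weight_cdf is not None:
                    w = weight_cdf.mean_kg
                elif fixed_weight_kg is not None:
                    w = fixed_weight_kg
                else:
                    raise ValueError("weight-based regimen needs a weight model")
                n_units = units_dispensed(weight_based_dose(ev.amount, w),
                                          unit.strength_mg, method)
        else:
            n_units = units_dispensed(ev.amount, unit.strength_mg, method)
        total += n_units * unit.price_per_unit
    if strategy.with_methotrexate and not costs.mtx_cost_zero:
        mtx = costs.drug_unit_costs["MTX"]
        weeks = end_week - start_week
        dose_per_week = costs.mtx_weekly_dose_mg
        n = units_dispensed(dose_per_week, mtx.strength_mg, method) * weeks
        total += n * mtx.price_per_unit
    return total


def administration_and_monitoring_cost(strategy: TreatmentStrategy, start_week: float,
                                       end_week: float, costs: CostInputs,
                                       first_cycle: bool = False) -> float:
    """IV administration per infusion plus the configured monitoring
    schedule (€, undiscounted).  Subcutaneous and oral routes carry no
    administration cost."""
    total = 0.0
    if strategy.regimen.route.value == "intravenous":
        n_infusions = len(doses_in_window(strategy.regimen, start_week, end_week))
        total += n_infusions * costs.iv_administration_cost
    total += monitoring_cost(costs, (end_week - start_week) / (26.0), first_cycle)
    return total


def monitoring_cost(costs: CostInputs, cycle_fraction_of_6mo: float = 1.0,
                    first_cycle: bool = False) -> float:
    """Monitoring schedule cost for one cycle (counts are per 6-month cycle,
    scaled for shorter cycles; one-off baseline items added in cycle 0)."""
    total = sum(costs.monitoring_item_costs[item] * n * cycle_fraction_of_6mo
                for item, n in costs.monitoring_per_cycle.items())
    if first_cycle:
        total += sum(costs.monitoring_item_costs[item] * n
                     for item, n in costs.first_cycle_items.items())
    return total


def haq_band_cost_per_year(haq: float, band_costs: list[float]) -> float:
    """Annual disease-related resource cost by HAQ band ([0,0.5) … [2.5,3])."""
    idx = min(5, int(np.clip(haq, 0.0, 3.0) / 0.5))
    return band_costs[idx]


def inflate_then_discount(cost: float, years_from_start: float,
                          settings: ModelSettings) -> float:
    """Apply inflation from the cost year forward, then discount to present
    value: cost · (1+inflation)^t · (1+discount)^(−t)."""
    if years_from_start < 0:
        raise ValueError("years_from_start must be >= 0")
    t = years_from_start
    return cost * (1.0 + settings.inflation_rate) ** t \
        * (1.0 + settings.discount_rate_costs) ** (-t)


def accumulate_costs(occupancy: np.ndarray, cost_table: np.ndarray,
                     cycle_start_years: np.ndarray, settings: ModelSettings,
                     cycle_length_years: np.ndarray | None = None) -> float:
    """Occupancy-weighted, inflated-and-discounted total cost over a trace.

    ``occupancy`` and ``cost_table`` are (n_cycles, n_states); the death
    state must carry zero cost.  Discount/inflation factors are evaluated
    at each cycle's start time (midpoint under half-cycle correction).
    """
    occupancy = np.asarray(occupancy, float)
    cost_table = np.asarray(cost_table, float)
    if occupancy.shape != cost_table.shape:
        raise ValueError("occupancy and cost grids do not match")
    if len(cycle_start_years) != occupancy.shape[0]:
        raise ValueError("cycle grid length mismatch")
    t = np.asarray(cycle_start_years, float)
    if settings.half_cycle_correction and cycle_length_years is not None:
        t = t + np.asarray(cycle_length_years, float) / 2.0
    factor = ((1.0 + settings.inflation_rate) ** t
              * (1.0 + settings.discount_rate_costs) ** (-t))
    return float(((occupancy * cost_table).sum(axis=1) * factor).sum())
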