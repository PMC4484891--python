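"""Model configuration: domain types, validation, defaults and scenario overrides.

The model has no deposited data set — every input is a parameter.  This
module defines the typed configuration tree (validated with pydantic),
the base-case parameter set (2009 Spanish costing year), the provenance
registry distinguishing values printed in the source cost-utility study
("paper") from documented synthetic defaults ("default"), and the
registered one-way sensitivity-analysis scenarios.
"""

from __future__ import annotations

import copy
import warnings
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConfigError",
    "Regimen",
    "TreatmentStrategy",
    "ResponseRow",
    "ResponseEntry",
    "CostInputs",
    "DrugUnitCost",
    "UtilityInputs",
    "MortalityInputs",
    "PopulationProfile",
    "PSAInputs",
    "FollowupDrug",
    "ModelSettings",
    "ModelConfig",
    "load_model_config",
    "write_model_config",
    "default_parameter_set",
    "resolve_scenario",
    "registered_scenarios",
    "provenance",
]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema or invariant checks."""


class Route(str, Enum):
    subcutaneous = "subcutaneous"
    intravenous = "intravenous"
    oral = "oral"
    intramuscular = "intramuscular"


class CostingMethod(str, Enum):
    per_unit = "per_unit"
    per_mg = "per_mg"


class Perspective(str, Enum):
    payer = "payer"
    societal = "societal"


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModelSettings(_Base):
    horizon_years: float = 45.0
    response_assessment_months: int = 6
    cycle_months_after_year1: int = 6
    discount_rate_costs: float = 0.035
    discount_rate_outcomes: float = 0.035
    inflation_rate: float = 0.03
    cost_year: int = 2009
    wtp_threshold: float = 30_000.0
    costing_method: CostingMethod = CostingMethod.per_unit
    perspective: Perspective = Perspective.payer
    half_cycle_correction: bool = False

    @model_validator(mode="after")
    def _invariants(self) -> "ModelSettings":
        if not (0 < self.horizon_years <= 100):
            raise ValueError(f"horizon_years must be in (0, 100], got {self.horizon_years}")
        for name in ("discount_rate_costs", "discount_rate_outcomes", "inflation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.2):
                raise ValueError(f"{name} must be in [0, 0.2], got {v}")
        if self.response_assessment_months not in (3, 6):
            raise ValueError(
                f"response_assessment_months must be 3 or 6, got {self.response_assessment_months}"
            )
        if 12 % self.response_assessment_months:
            raise ValueError("response_assessment_months must divide 12")
        return self


class Regimen(_Base):
    """Dosing schedule.  Amounts are mg, or mg/kg when ``mg_per_kg`` is set
    (then loading amounts are mg/kg too)."""

    loading_doses: list[tuple[float, float]] = Field(default_factory=list)
    maintenance_dose_mg: Optional[float] = None
    mg_per_kg: Optional[float] = None
    maintenance_interval_weeks: float
    maintenance_start_week: float
    route: Route

    @model_validator(mode="after")
    def _invariants(self) -> "Regimen":
        if (self.maintenance_dose_mg is None) == (self.mg_per_kg is None):
            raise ValueError("exactly one of maintenance_dose_mg / mg_per_kg must be set")
        dose = self.maintenance_dose_mg if self.maintenance_dose_mg is not None else self.mg_per_kg
        if dose <= 0:
            raise ValueError("maintenance dose must be positive")
        if self.maintenance_interval_weeks <= 0:
            raise ValueError("maintenance_interval_weeks must be positive")
        weeks = [w for w, _ in self.loading_doses]
        if any(w2 <= w1 for w1, w2 in zip(weeks, weeks[1:])):
            raise ValueError("loading-dose weeks must be strictly increasing")
        if any(d <= 0 for _, d in self.loading_doses):
            raise ValueError("loading doses must be positive")
        return self

    @property
    def weight_based(self) -> bool:
        return self.mg_per_kg is not None


class TreatmentStrategy(_Base):
    name: str
    drug: str
    regimen: Regimen
    with_methotrexate: bool
    response_key: str
    median_duration_months: float = 37.0
    followup_sequence: list[str] = Field(
        default_factory=lambda: list(DEFAULT_FOLLOWUP_SEQUENCE)
    )

    @model_validator(mode="after")
    def _invariants(self) -> "TreatmentStrategy":
        if self.median_duration_months <= 0:
            raise ValueError("median_duration_months must be positive")
        if not self.followup_sequence or self.followup_sequence[-1] != "palliation":
            raise ValueError("followup_sequence must end with 'palliation'")
        return self


class ResponseRow(_Base):
    """Cumulative ACR response fractions (ACR70 ⊆ ACR50 ⊆ ACR20).

    Stored verbatim as printed; non-monotone rows trigger a warning, not an
    error, because the published transition table is consumed as-is and
    any overlap is clamped downstream when converting to exclusive
    categories."""

    acr20: float
    acr50: Optional[float] = None
    acr70: Optional[float] = None

    @model_validator(mode="after")
    def _invariants(self) -> "ResponseRow":
        for name in ("acr20", "acr50", "acr70"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.acr50 is not None and self.acr70 is not None:
            if not (self.acr70 <= self.acr50 <= self.acr20):
                warnings.warn(
                    f"non-monotone cumulative ACR row ({self.acr20}, {self.acr50}, "
                    f"{self.acr70}); will be clamped when made exclusive",
                    stacklevel=2,
                )
        return self


class ResponseEntry(_Base):
    m3: Optional[ResponseRow] = None
    m6: ResponseRow

    def at_months(self, months: int) -> ResponseRow:
        if months == 6:
            return self.m6
        if months == 3:
            if self.m3 is None:
                raise ConfigError("no 3-month response row configured")
            row = self.m3
            if row.acr50 is None or row.acr70 is None:
                # impute missing cumulative fractions from the 6-month
                # category ratios (printed table has gaps at 3 months)
                r50 = self.m6.acr50 / self.m6.acr20 if self.m6.acr20 else 0.0
                r70 = self.m6.acr70 / self.m6.acr20 if self.m6.acr20 else 0.0
                row = ResponseRow(
                    acr20=row.acr20,
                    acr50=row.acr50 if row.acr50 is not None else row.acr20 * r50,
                    acr70=row.acr70 if row.acr70 is not None else row.acr20 * r70,
                )
            return row
        raise ConfigError(f"response assessment must be at 3 or 6 months, got {months}")


class DrugUnitCost(_Base):
    cost: float
    strength_mg: float
    units_per_pack: int = 1
    presentation: str = ""

    @model_validator(mode="after")
    def _invariants(self) -> "DrugUnitCost":
        if self.cost < 0:
            raise ValueError("cost must be non-negative")
        if self.strength_mg <= 0:
            raise ValueError("strength_mg must be positive")
        return self

    @property
    def price_per_unit(self) -> float:
        """Price of one dispensing unit (syringe, vial, tablet)."""
        return self.cost / self.units_per_pack

    @property
    def price_per_mg(self) -> float:
        return self.cost / (self.units_per_pack * self.strength_mg)


class CostInputs(_Base):
    drug_unit_costs: dict[str, DrugUnitCost]
    iv_administration_cost: float = 232.80
    monitoring_item_costs: dict[str, float]
    monitoring_per_cycle: dict[str, float]
    first_cycle_items: dict[str, float] = Field(default_factory=dict)
    haq_band_costs: list[float]
    mtx_cost_zero: bool = True
    mtx_weekly_dose_mg: float = 15.0
    societal_increment_per_cycle: float = 0.0

    @model_validator(mode="after")
    def _invariants(self) -> "CostInputs":
        if self.iv_administration_cost < 0:
            raise ValueError("iv_administration_cost must be non-negative")
        if len(self.haq_band_costs) != 6:
            raise ValueError("haq_band_costs must give 6 HAQ bands ([0,0.5) … [2.5,3])")
        if any(c < 0 for c in self.haq_band_costs):
            raise ValueError("haq_band_costs must be non-negative")
        for k, v in self.monitoring_item_costs.items():
            if v < 0:
                raise ValueError(f"monitoring item cost for {k!r} must be non-negative")
        return self


class UtilityInputs(_Base):
    baseline_utility: float = 0.38
    response_gain_override: Optional[dict[str, float]] = None
    front_load_fraction: float = 0.8
    front_load_week: float = 4.0
    continuation_gain_fraction: float = 0.1
    bansback_coefficient: float = -0.2102
    rebound_fraction: float = 1.0
    haq_progression_on_biologic: float = 0.0
    haq_progression_conventional: float = 0.045
    haq_progression_palliative: float = 0.06
    haq_max: float = 3.0
    utility_floor: float = 0.0
    utility_ceiling: float = 1.0
    qol_instrument: str = "eq5d"

    @model_validator(mode="after")
    def _invariants(self) -> "UtilityInputs":
        for name in ("front_load_fraction", "continuation_gain_fraction", "rebound_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.utility_floor <= self.baseline_utility <= self.utility_ceiling <= 1.0):
            raise ValueError("need utility_floor <= baseline_utility <= utility_ceiling <= 1")
        if not (0.0 < self.haq_max <= 3.0):
            raise ValueError("haq_max must be in (0, 3]")
        if self.qol_instrument not in ("eq5d", "haq"):
            raise ValueError("qol_instrument must be 'eq5d' or 'haq'")
        return self


class MortalityInputs(_Base):
    rr_per_haq_unit: float = 1.330
    rr_ci: tuple[float, float] = (1.099, 1.610)
    enabled: bool = True
    life_table_path: Optional[str] = None

    @model_validator(mode="after")
    def _invariants(self) -> "MortalityInputs":
        if self.rr_per_haq_unit <= 0:
            raise ValueError("rr_per_haq_unit must be positive")
        if not (0 < self.rr_ci[0] <= self.rr_ci[1]):
            raise ValueError("rr_ci must be an increasing positive pair")
        return self


class PopulationProfile(_Base):
    mean_age: float = 52.165
    proportion_female: float = 1506 / 1821
    mean_weight_kg: float = 81.4
    weight_spread_kg: float = 15.0
    baseline_haq: float = 1.624
    n_prior_dmards: float = 2.258
    disease_duration_years: float = 6.557

    @model_validator(mode="after")
    def _invariants(self) -> "PopulationProfile":
        if not (0.0 <= self.proportion_female <= 1.0):
            raise ValueError("proportion_female must be in [0, 1]")
        if not (0.0 <= self.baseline_haq <= 3.0):
            raise ValueError("baseline_haq must be in [0, 3]")
        if self.mean_weight_kg <= 0 or self.weight_spread_kg <= 0:
            raise ValueError("weight parameters must be positive")
        if not (18.0 <= self.mean_age <= 100.0):
            raise ValueError("mean_age must be in [18, 100]")
        return self


class NormalParam(_Base):
    """Normal PSA parameter given as mean plus a 95% confidence interval
    on the mean; the simulation standard deviation is (hi − lo)/(2·1.96)."""

    mean: float
    ci: tuple[float, float]

    @property
    def sd(self) -> float:
        lo, hi = self.ci
        return (hi - lo) / (2 * 1.959963984540054)

    @model_validator(mode="after")
    def _invariants(self) -> "NormalParam":
        if self.ci[1] < self.ci[0]:
            raise ValueError("CI must be ordered (lo, hi)")
        return self


class PSAInputs(_Base):
    n_draws: int = 1000
    response_logodds_se: float = 0.15
    age: NormalParam = NormalParam(mean=52.165, ci=(51.893, 52.4378))
    baseline_haq: NormalParam = NormalParam(mean=1.624, ci=(1.610, 1.638))
    n_prior_dmards: NormalParam = NormalParam(mean=2.258, ci=(2.207, 2.308))
    disease_duration: NormalParam = NormalParam(mean=6.557, ci=(6.351, 6.763))
    anti_ccp_positive: NormalParam = NormalParam(mean=1.676, ci=(1.611, 1.741))
    anti_ccp_negative: NormalParam = NormalParam(mean=1.621, ci=(1.606, 1.635))
    utility_weight: NormalParam = NormalParam(mean=0.380, ci=(0.372, 0.388))
    gender_trial_n: int = 1821
    gender_trial_female: int = 1506

    @model_validator(mode="after")
    def _invariants(self) -> "PSAInputs":
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.response_logodds_se <= 0:
            raise ValueError("response_logodds_se must be positive")
        if not (0 < self.gender_trial_female < self.gender_trial_n):
            raise ValueError("gender beta counts must satisfy 0 < n < N")
        return self

    @property
    def gender_beta_shapes(self) -> tuple[float, float]:
        n, nf = self.gender_trial_n, self.gender_trial_female
        return float(nf), float(n - nf)


class FollowupDrug(_Base):
    """A conventional DMARD line in the follow-up sequence."""

    response_6mo: ResponseRow
    median_duration_months: float
    daily_dose_mg: float
    cost_key: str
    rationale: str = ""

    @model_validator(mode="after")
    def _invariants(self) -> "FollowupDrug":
        if self.median_duration_months <= 0:
            raise ValueError("median_duration_months must be positive")
        if self.daily_dose_mg < 0:
            raise ValueError("daily_dose_mg must be non-negative")
        return self


class ModelConfig(_Base):
    settings: ModelSettings
    population: PopulationProfile
    utilities: UtilityInputs
    mortality: MortalityInputs
    costs: CostInputs
    response: dict[str, ResponseEntry]
    followup: dict[str, FollowupDrug]
    haq_change_by_acr_category: dict[str, float]
    discontinuation_efficacy_split: float = 0.5
    strategies: list[TreatmentStrategy]
    psa: PSAInputs = Field(default_factory=PSAInputs)

    @model_validator(mode="after")
    def _invariants(self) -> "ModelConfig":
        for s in self.strategies:
            if s.response_key not in self.response:
                raise ValueError(f"strategy {s.name!r} references unknown response row "
                                 f"{s.response_key!r}")
            if s.drug not in self.costs.drug_unit_costs:
                raise ValueError(f"strategy {s.name!r} drug {s.drug!r} has no unit cost")
            for line in s.followup_sequence[:-1]:
                if line not in self.followup:
                    raise ValueError(f"follow-up drug {line!r} is not configured")
        for cat in ("none", "acr20", "acr50", "acr70"):
            if cat not in self.haq_change_by_acr_category:
                raise ValueError(f"haq_change_by_acr_category missing {cat!r}")
        if not (0.0 <= self.discontinuation_efficacy_split <= 1.0):
            raise ValueError("discontinuation_efficacy_split must be in [0, 1]")
        return self

    def strategy(self, name: str) -> TreatmentStrategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}; have "
                       f"{[s.name for s in self.strategies]}")


DEFAULT_FOLLOWUP_SEQUENCE = (
    "sulfasalazine",
    "leflunomide",
    "gold sodium thiomalate",
    "hydroxychloroquine",
    "azathioprine",
    "cyclosporine",
    "penicillamine",
    "palliation",
)


# --------------------------------------------------------------------------
# default parameter set (base case)

def _regimen_czp() -> Regimen:
    # 400 mg at weeks 0, 2 and 4, then 200 mg every 2 weeks
    return Regimen(
        loading_doses=[(0, 400.0), (2, 400.0), (4, 400.0)],
        maintenance_dose_mg=200.0,
        maintenance_interval_weeks=2.0,
        maintenance_start_week=6.0,
        route=Route.subcutaneous,
    )


def _regimen_ifx(mg_per_kg: float) -> Regimen:
    # mg/kg at weeks 0, 2, 6 and every 8 weeks thereafter
    return Regimen(
        loading_doses=[(0, mg_per_kg), (2, mg_per_kg), (6, mg_per_kg)],
        mg_per_kg=mg_per_kg,
        maintenance_interval_weeks=8.0,
        maintenance_start_week=14.0,
        route=Route.intravenous,
    )


def _regimen_ada(interval_weeks: float) -> Regimen:
    return Regimen(
        maintenance_dose_mg=40.0,
        maintenance_interval_weeks=interval_weeks,
        maintenance_start_week=0.0,
        route=Route.subcutaneous,
    )


def _regimen_eta() -> Regimen:
    # 25 mg twice weekly
    return Regimen(
        maintenance_dose_mg=25.0,
        maintenance_interval_weeks=0.5,
        maintenance_start_week=0.0,
        route=Route.subcutaneous,
    )


def default_parameter_set() -> ModelConfig:
    """The base-case configuration.

    Printed inputs (transition probabilities, unit costs, utility and
    mortality coefficients, cohort characteristics) carry provenance
    "paper"; everything the source analysis cites but does not print is
    filled from the synthetic defaults registry with provenance "default"
    (see :func:`racua.synthetic.defaults_registry` and :func:`provenance`).
    """
    from . import synthetic  # deferred: synthetic imports types from here

    reg = synthetic.defaults_registry()

    response = {
        "MTX": ResponseEntry(
            m3=ResponseRow(acr20=0.215, acr50=0.072, acr70=0.020),
            m6=ResponseRow(acr20=0.242, acr50=0.097, acr70=0.037),
        ),
        "CZP+MTX": ResponseEntry(
            m3=ResponseRow(acr20=0.711, acr50=0.359, acr70=0.216),
            m6=ResponseRow(acr20=0.772, acr50=0.492, acr70=0.282),
        ),
        "ADA+MTX": ResponseEntry(
            m3=ResponseRow(acr20=0.708),  # ACR50/70 not reported at 3 months
            m6=ResponseRow(acr20=0.610, acr50=0.418, acr70=0.197),
        ),
        "ETA+MTX": ResponseEntry(
            m3=ResponseRow(acr20=0.664, acr50=0.611, acr70=0.237),
            m6=ResponseRow(acr20=0.685, acr50=0.664, acr70=0.307),
        ),
        "IFX+MTX": ResponseEntry(
            m3=ResponseRow(acr20=0.586, acr50=0.270, acr70=0.196),
            m6=ResponseRow(acr20=0.482, acr50=0.261, acr70=0.113),
        ),
        "placebo": ResponseEntry(
            m3=ResponseRow(acr20=0.140, acr50=0.032, acr70=0.011),
            m6=ResponseRow(acr20=0.131, acr50=0.057, acr70=0.010),
        ),
        "CZP": ResponseEntry(
            m3=ResponseRow(acr20=0.533, acr50=0.451, acr70=0.116),
            m6=ResponseRow(acr20=0.559, acr50=0.314, acr70=0.123),
        ),
        "ADA": ResponseEntry(
            m3=ResponseRow(acr20=0.553, acr50=0.257, acr70=0.164),
            m6=ResponseRow(acr20=0.390, acr50=0.188, acr70=0.085),
        ),
        "ETA": ResponseEntry(
            m3=ResponseRow(acr20=0.462, acr50=0.214, acr70=0.051),
            m6=ResponseRow(acr20=0.620, acr50=0.423, acr70=0.129),
        ),
    }

    drug_costs = {
        "CZP": DrugUnitCost(cost=474.00, strength_mg=200, presentation="pre-filled syringe"),
        "IFX": DrugUnitCost(cost=536.28, strength_mg=100, presentation="vial"),
        "ADA": DrugUnitCost(cost=514.15, strength_mg=40, presentation="pre-filled syringe"),
        "ETA": DrugUnitCost(cost=118.40, strength_mg=25, presentation="pre-filled syringe"),
        "MTX": DrugUnitCost(cost=2.11, strength_mg=3, units_per_pack=50, presentation="tablets"),
        "azathioprine": DrugUnitCost(cost=5.78, strength_mg=50, units_per_pack=50,
                                     presentation="tablets"),
        "cyclosporine": DrugUnitCost(cost=65.90, strength_mg=100, units_per_pack=30,
                                     presentation="tablets"),
        "gold sodium thiomalate": DrugUnitCost(cost=6.73, strength_mg=50, presentation="vial"),
        "hydroxychloroquine": DrugUnitCost(cost=7.33, strength_mg=200, units_per_pack=30,
                                           presentation="tablets"),
        "leflunomide": DrugUnitCost(cost=57.59, strength_mg=20, units_per_pack=30,
                                    presentation="tablets"),
        "penicillamine": DrugUnitCost(cost=6.75, strength_mg=250, units_per_pack=30,
                                      presentation="tablets"),
        "sulfasalazine": DrugUnitCost(cost=2.38, strength_mg=500, units_per_pack=50,
                                      presentation="tablets"),
        "palliation": DrugUnitCost(cost=0.0, strength_mg=1, presentation="-"),
        "methylprednisolone": DrugUnitCost(cost=1.59, strength_mg=40, presentation="vial"),
    }

    monitoring_items = {
        "primary_care_physician": 26.78,
        "nurse_outpatient": 23.77,
        "hospital_nurse_hour": 13.19,
        "rheumatologist": 99.94,
        "hospital_pharmacist": 105.66,
        "complete_blood_count": 6.37,
        "sedimentation_rate": 3.56,
        "clinical_chemistry": 6.31,
        "urinalysis": 4.00,
        "chest_xray": 11.61,
    }

    strategies = [
        TreatmentStrategy(name="CZP+MTX", drug="CZP", regimen=_regimen_czp(),
                          with_methotrexate=True, response_key="CZP+MTX"),
        TreatmentStrategy(name="ADA+MTX (every 2 weeks)", drug="ADA",
                          regimen=_regimen_ada(2.0), with_methotrexate=True,
                          response_key="ADA+MTX"),
        TreatmentStrategy(name="ADA+MTX (weekly)", drug="ADA",
                          regimen=_regimen_ada(1.0), with_methotrexate=True,
                          response_key="ADA+MTX"),
        TreatmentStrategy(name="ETA+MTX", drug="ETA", regimen=_regimen_eta(),
                          with_methotrexate=True, response_key="ETA+MTX"),
        TreatmentStrategy(name="IFX (3 mg/kg)+MTX", drug="IFX", regimen=_regimen_ifx(3.0),
                          with_methotrexate=True, response_key="IFX+MTX"),
        TreatmentStrategy(name="IFX (5 mg/kg)+MTX", drug="IFX", regimen=_regimen_ifx(5.0),
                          with_methotrexate=True, response_key="IFX+MTX"),
        TreatmentStrategy(name="CZP", drug="CZP", regimen=_regimen_czp(),
                          with_methotrexate=False, response_key="CZP"),
        TreatmentStrategy(name="ADA (every 2 weeks)", drug="ADA",
                          regimen=_regimen_ada(2.0), with_methotrexate=False,
                          response_key="ADA"),
        TreatmentStrategy(name="ADA (weekly)", drug="ADA",
                          regimen=_regimen_ada(1.0), with_methotrexate=False,
                          response_key="ADA"),
        TreatmentStrategy(name="ETA", drug="ETA", regimen=_regimen_eta(),
                          with_methotrexate=False, response_key="ETA"),
    ]

    return ModelConfig(
        settings=ModelSettings(),
        population=PopulationProfile(),
        utilities=UtilityInputs(
            continuation_gain_fraction=reg.continuation_gain_fraction,
            haq_progression_conventional=reg.haq_progression_conventional,
            haq_progression_palliative=reg.haq_progression_palliative,
        ),
        mortality=MortalityInputs(),
        costs=CostInputs(
            drug_unit_costs=drug_costs,
            monitoring_item_costs=monitoring_items,
            monitoring_per_cycle={
                "rheumatologist": 2,
                "complete_blood_count": 2,
                "sedimentation_rate": 2,
                "clinical_chemistry": 2,
                "urinalysis": 2,
            },
            first_cycle_items={"chest_xray": 1},
            haq_band_costs=list(reg.haq_band_costs),
        ),
        response=response,
        followup={
            name: FollowupDrug(
                response_6mo=ResponseRow(**reg.followup_response_6mo[name]),
                median_duration_months=reg.followup_median_duration_months[name],
                daily_dose_mg=reg.followup_daily_dose_mg[name],
                cost_key=name,
                rationale=reg.rationale[f"followup.{name}"],
            )
            for name in DEFAULT_FOLLOWUP_SEQUENCE[:-1]
        },
        haq_change_by_acr_category=dict(reg.haq_change_by_acr_category),
        discontinuation_efficacy_split=reg.discontinuation_efficacy_split,
        strategies=strategies,
        psa=PSAInputs(),
    )


# --------------------------------------------------------------------------
# provenance

#: Dotted config paths whose values are printed in the source study.
PAPER_KEYS = frozenset({
    "settings.horizon_years", "settings.response_assessment_months",
    "settings.discount_rate_costs", "settings.discount_rate_outcomes",
    "settings.inflation_rate", "settings.cost_year", "settings.wtp_threshold",
    "settings.costing_method",
    "population.mean_age", "population.proportion_female",
    "population.mean_weight_kg", "population.baseline_haq",
    "population.n_prior_dmards", "population.disease_duration_years",
    "utilities.baseline_utility", "utilities.front_load_fraction",
    "utilities.front_load_week", "utilities.bansback_coefficient",
    "utilities.rebound_fraction",
    "mortality.rr_per_haq_unit", "mortality.rr_ci",
    "costs.iv_administration_cost", "costs.mtx_cost_zero",
    "psa.n_draws", "psa.age", "psa.baseline_haq", "psa.n_prior_dmards",
    "psa.disease_duration", "psa.anti_ccp_positive", "psa.anti_ccp_negative",
    "psa.utility_weight", "psa.gender_trial_n", "psa.gender_trial_female",
} | {f"response.{k}" for k in (
    "MTX", "CZP+MTX", "ADA+MTX", "ETA+MTX", "IFX+MTX",
    "placebo", "CZP", "ADA", "ETA")}
  | {f"costs.drug_unit_costs.{k}" for k in (
    "CZP", "IFX", "ADA", "ETA", "MTX", "azathioprine", "cyclosporine",
    "gold sodium thiomalate", "hydroxychloroquine", "leflunomide",
    "penicillamine", "sulfasalazine", "palliation", "methylprednisolone")}
  | {f"costs.monitoring_item_costs.{k}" for k in (
    "primary_care_physician", "nurse_outpatient", "hospital_nurse_hour",
    "rheumatologist", "hospital_pharmacist", "complete_blood_count",
    "sedimentation_rate", "clinical_chemistry", "urinalysis", "chest_xray")}
)

#: Dotted config paths filled from the synthetic defaults registry.
DEFAULT_KEYS = frozenset({
    "utilities.continuation_gain_fraction",
    "utilities.haq_progression_on_biologic",
    "utilities.haq_progression_conventional",
    "utilities.haq_progression_palliative",
    "costs.haq_band_costs", "costs.monitoring_per_cycle",
    "costs.first_cycle_items", "costs.mtx_weekly_dose_mg",
    "population.weight_spread_kg",
    "haq_change_by_acr_category", "discontinuation_efficacy_split",
    "psa.response_logodds_se", "mortality.life_table_path",
} | {f"followup.{k}" for k in DEFAULT_FOLLOWUP_SEQUENCE[:-1]})


def provenance(key: str) -> str:
    """Return ``"paper"`` or ``"default"`` for a dotted config path.

    Lookup falls back to the longest registered prefix, so e.g.
    ``provenance("response.CZP+MTX.m6.acr20") == "paper"``.
    """
    parts = key.split(".")
    for i in range(len(parts), 0, -1):
        prefix = ".".join(parts[:i])
        if prefix in PAPER_KEYS:
            return "paper"
        if prefix in DEFAULT_KEYS:
            return "default"
    raise KeyError(f"no provenance registered for {key!r}")


# --------------------------------------------------------------------------
# file I/O

def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    Unknown keys are rejected; invariant violations raise
    :class:`ConfigError` naming the offending field and value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid model configuration ({path}): {details}") from exc


def write_model_config(config: ModelConfig, path: str | Path) -> None:
    """Serialise a configuration to YAML (round-trips with ``load_model_config``)."""
    payload = config.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def default_config_path() -> Path:
    """Path of the shipped base-case configuration file."""
    return Path(__file__).parent / "data" / "default_config.yaml"


# --------------------------------------------------------------------------
# scenario registry (one-way sensitivity analyses)

def _scenarios() -> dict[str, dict[str, object]]:
    iv_pivot = 214.54  # sensitivity pivot for the IV administration cost
    return {
        "horizon_5y": {"settings.horizon_years": 5},
        "horizon_10y": {"settings.horizon_years": 10},
        "discount_c15_o15": {"settings.discount_rate_costs": 0.015,
                             "settings.discount_rate_outcomes": 0.015},
        "discount_c15_o60": {"settings.discount_rate_costs": 0.015,
                             "settings.discount_rate_outcomes": 0.06},
        "discount_c60_o15": {"settings.discount_rate_costs": 0.06,
                             "settings.discount_rate_outcomes": 0.015},
        "discount_c60_o60": {"settings.discount_rate_costs": 0.06,
                             "settings.discount_rate_outcomes": 0.06},
        "inflation_0": {"settings.inflation_rate": 0.0},
        "acr_3mo": {"settings.response_assessment_months": 3},
        "haq_base_1_61": {"population.baseline_haq": 1.61},
        "haq_base_2_5": {"population.baseline_haq": 2.5},
        "rebound_50": {"utilities.rebound_fraction": 0.5},
        "per_mg_costing": {"settings.costing_method": "per_mg"},
        "qol_haq": {"utilities.qol_instrument": "haq"},
        "mortality_off": {"mortality.enabled": False},
        "iv_admin_plus20": {"costs.iv_administration_cost": round(iv_pivot * 1.2, 2)},
        "iv_admin_minus20": {"costs.iv_administration_cost": round(iv_pivot * 0.8, 2)},
        "societal": {"settings.perspective": "societal"},
    }


def registered_scenarios() -> list[str]:
    return sorted(_scenarios())


def resolve_scenario(base: ModelConfig,
                     overrides: str | dict[str, object] | None) -> ModelConfig:
    """Return a new config differing from ``base`` only in the overridden fields.

    ``overrides`` is a registered scenario name, an explicit mapping of
    dotted paths to values, or None/empty (identity).  ``base`` is never
    mutated; resolving the same scenario twice is idempotent.
    """
    if isinstance(overrides, str):
        reg = _scenarios()
        if overrides not in reg:
            raise KeyError(
                f"unknown scenario {overrides!r}; registered: {sorted(reg)}"
            )
        overrides = reg[overrides]
    new = base.model_copy(deep=True)
    if overrides:
        for dotted, value in overrides.items():
            obj = new
            *head, last = dotted.split(".")
            for part in head:
                obj = getattr(obj, part)
            setattr(obj, last, copy.deepcopy(value))
    return ModelConfig.model_validate(new.model_dump(mode="json"))
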