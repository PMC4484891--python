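"""Cost-utility analysis: strategy evaluation, incremental analysis with
dominance classification, one-way sensitivity scenarios, and probabilistic
sensitivity analysis with CEAC / cost-effectiveness-plane outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import costs as cost_model
from .config import (CostingMethod, ModelConfig, Perspective, ResponseRow,
                     TreatmentStrategy, resolve_scenario)
from .engine import CohortTrace, run_cohort
from .synthetic import LifeTable, WeightCDF, make_synthetic_life_table, make_weight_cdf
from .utility import (WEEKS_PER_MONTH, discounted_qalys,
                      first_cycle_utility_profile, response_gain)

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyResult",
    "IncrementalResult",
    "Dominance",
    "PSAResult",
    "evaluate_strategy",
    "incremental_analysis",
    "classify_dominance",
    "run_owsa",
    "sample_psa_draw",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class StrategyResult:
    name: str
    cost: float
    qalys: float
    trace: CohortTrace | None = None


class Dominance(str, Enum):
    reference_dominant = "reference_dominant"
    comparator_dominant = "comparator_dominant"
    icer_defined = "icer_defined"
    equal = "equal"


@dataclass(frozen=True)
class IncrementalResult:
    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: Dominance


def _build_cost_table(config: ModelConfig, strategy: TreatmentStrategy,
                      trace: CohortTrace,
                      fixed_weight_kg: float | None,
                      weight_cdf: WeightCDF | None) -> np.ndarray:
    """Undiscounted per-cycle per-state cost table (€ at cost-year prices)."""
    space = trace.space
    n_c = len(trace.cycle_start_years)
    table = np.zeros((n_c, space.n))
    c_in = config.costs
    method = config.settings.costing_method
    starts_w = trace.cycle_start_years * 12.0 * WEEKS_PER_MONTH
    lengths_w = trace.cycle_length_years * 12.0 * WEEKS_PER_MONTH

    per_mg = {line: c_in.drug_unit_costs[config.followup[line].cost_key].price_per_mg
              for line in space.lines}
    daily = {line: config.followup[line].daily_dose_mg for line in space.lines}

    for c in range(n_c):
        w0, w1 = starts_w[c], starts_w[c] + lengths_w[c]
        dt_y = trace.cycle_length_years[c]
        days = dt_y * 365.25
        frac6 = trace.cycle_length_years[c] / 0.5
        drug = cost_model.cycle_drug_cost(
            strategy, w0, w1, c_in, config.settings,
            fixed_weight_kg=fixed_weight_kg, weight_cdf=weight_cdf)
        admin = cost_model.administration_and_monitoring_cost(
            strategy, w0, w1, c_in, first_cycle=(c == 0))
        for s in (space.ENTRY, *space.ACR):
            table[c, s] = drug + admin
        mon = cost_model.monitoring_cost(c_in, frac6, first_cycle=False)
        for k, line in enumerate(space.lines):
            line_drug = daily[line] * days * per_mg[line]
            for s in (space.assess(k), space.cont(k)):
                table[c, s] = line_drug + mon
        # disease-cost by HAQ band, all living states
        for s in range(space.n):
            if s == space.DEATH:
                continue
            band = cost_model.haq_band_cost_per_year(trace.haq[c, s], c_in.haq_band_costs)
            table[c, s] += band * dt_y
            if config.settings.perspective is Perspective.societal:
                table[c, s] += c_in.societal_increment_per_cycle * frac6
    return table


def evaluate_strategy(config: ModelConfig, strategy: TreatmentStrategy | str,
                      life_table: LifeTable | None = None,
                      fixed_weight_kg: float | None = None,
                      weight_cdf: WeightCDF | None = None,
                      keep_trace: bool = False) -> StrategyResult:
    """Run the cohort model for one strategy and return discounted mean
    lifetime cost and QALYs.

    The base case doses weight-based drugs at the fixed cohort weight;
    pass ``weight_cdf`` to integrate vial counts over the weight
    distribution instead.
    """
    if isinstance(strategy, str):
        strategy = config.strategy(strategy)
    if fixed_weight_kg is None:
        fixed_weight_kg = config.population.mean_weight_kg
    life_table = life_table or make_synthetic_life_table()
    trace = run_cohort(config, strategy, life_table)
    settings = config.settings

    cost_table = _build_cost_table(config, strategy, trace, fixed_weight_kg, weight_cdf)
    total_cost = cost_model.accumulate_costs(
        trace.occupancy, cost_table, trace.cycle_start_years, settings,
        trace.cycle_length_years)

    qalys = discounted_qalys(
        trace.utility, trace.occupancy, trace.cycle_start_years,
        trace.cycle_length_years, settings.discount_rate_outcomes, settings)
    # first cycle: replace the flat baseline-utility block with the
    # response-conditional front-loaded profile
    u = config.utilities
    row = config.response[strategy.response_key].at_months(
        settings.response_assessment_months)
    from .engine import exclusive_response_probabilities
    p_none, p20, p50, p70 = exclusive_response_probabilities(
        row.acr20, row.acr50, row.acr70)
    dt0_y = trace.cycle_length_years[0]
    dt0_m = dt0_y * 12.0
    t0 = trace.cycle_start_years[0] + (dt0_y / 2.0 if settings.half_cycle_correction else 0.0)
    disc0 = (1.0 + settings.discount_rate_outcomes) ** (-t0)
    correction = 0.0
    for p_cat, cat in ((p20, "acr20"), (p50, "acr50"), (p70, "acr70")):
        if p_cat <= 0:
            continue
        gain = response_gain(cat, u, config.haq_change_by_acr_category)
        prof = first_cycle_utility_profile(u.baseline_utility, gain, dt0_m, u)
        correction += p_cat * (prof.integral_years() - u.baseline_utility * dt0_y)
    qalys += disc0 * correction

    return StrategyResult(name=strategy.name, cost=total_cost, qalys=qalys,
                          trace=trace if keep_trace else None)


def classify_dominance(delta_cost: float, delta_qaly: float) -> Dominance:
    """Sign-quadrant dominance of the reference over the comparator.

    Boundary zeros resolve toward weak dominance: a strategy that is
    cheaper at equal effect (or more effective at equal cost) dominates.
    """
    if delta_cost == 0 and delta_qaly == 0:
        return Dominance.equal
    if delta_cost <= 0 and delta_qaly >= 0:
        return Dominance.reference_dominant
    if delta_cost >= 0 and delta_qaly <= 0:
        return Dominance.comparator_dominant
    return Dominance.icer_defined


def incremental_analysis(ref: StrategyResult, comp: StrategyResult) -> IncrementalResult:
    """Incremental cost and QALYs of the reference over the comparator,
    with ICER (Δcost/ΔQALY) where both deltas share a nonzero sign."""
    dc = ref.cost - comp.cost
    dq = ref.qalys - comp.qalys
    dom = classify_dominance(dc, dq)
    icer = dc / dq if dom is Dominance.icer_defined else None
    return IncrementalResult(reference=ref.name, comparator=comp.name,
                             delta_cost=dc, delta_qaly=dq, icer=icer, dominance=dom)


def run_owsa(config: ModelConfig, scenarios: list[str],
             strategies: list[str] | None = None,
             reference: str = "CZP+MTX",
             life_table: LifeTable | None = None) -> pd.DataFrame:
    """One row of incremental results per (scenario, comparator).

    Each scenario resolves a registered override set against the base
    configuration (audited: only the named fields differ) and re-runs the
    full model.
    """
    life_table = life_table or make_synthetic_life_table()
    if strategies is None:
        strategies = [s.name for s in config.strategies if s.name != reference]
    rows = []
    for scen in ["base_case"] + list(scenarios):
        cfg = config if scen == "base_case" else resolve_scenario(config, scen)
        ref_res = evaluate_strategy(cfg, reference, life_table)
        for comp in strategies:
            inc = incremental_analysis(ref_res, evaluate_strategy(cfg, comp, life_table))
            rows.append({
                "scenario": scen, "reference": reference, "comparator": comp,
                "ref_cost": ref_res.cost, "ref_qalys": ref_res.qalys,
                "delta_cost": inc.delta_cost, "delta_qaly": inc.delta_qaly,
                "icer": inc.icer, "dominance": inc.dominance.value,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass(frozen=True)
class PSADraw:
    response: dict[str, tuple[float, float, float]]   # per response key (used timepoint)
    mortality_rr: float
    age: float
    proportion_female: float
    weight_kg: float
    baseline_haq: float
    utility_weight: float
    n_prior_dmards: float
    disease_duration: float
    anti_ccp_positive: float
    anti_ccp_negative: float


def _lognormal_rr_params(rr: float, ci: tuple[float, float]) -> tuple[float, float]:
    lo, hi = ci
    return float(np.log(rr)), float((np.log(hi) - np.log(lo)) / (2 * 1.959963984540054))


def sample_psa_draw(config: ModelConfig, rng: np.random.Generator) -> PSADraw:
    """One joint parameter draw.

    Response fractions are perturbed on the log-odds scale, the mortality
    RR is lognormal with parameters implied by its point estimate and CI,
    gender is beta, weight comes from the weight distribution; baseline
    characteristics are normal.  Every drawn fraction lands in (0, 1).
    """
    psa = config.psa
    months = config.settings.response_assessment_months
    resp = {}
    for key, entry in config.response.items():
        row = entry.at_months(months)
        drawn = []
        for p in (row.acr20, row.acr50, row.acr70):
            p = min(max(p, 1e-9), 1 - 1e-9)
            drawn.append(float(expit(logit(p) + rng.normal(0.0, psa.response_logodds_se))))
        resp[key] = tuple(drawn)
    mu, sigma = _lognormal_rr_params(config.mortality.rr_per_haq_unit,
                                     config.mortality.rr_ci)
    a, b = psa.gender_beta_shapes
    wcdf = make_weight_cdf(config.population.mean_weight_kg,
                           config.population.weight_spread_kg)
    return PSADraw(
        response=resp,
        mortality_rr=float(np.exp(rng.normal(mu, sigma))),
        age=float(np.clip(rng.normal(psa.age.mean, psa.age.sd), 18.0, 90.0)),
        proportion_female=float(rng.beta(a, b)),
        weight_kg=float(wcdf.quantile(rng.uniform(1e-12, 1.0))),
        baseline_haq=float(np.clip(rng.normal(psa.baseline_haq.mean,
                                              psa.baseline_haq.sd), 0.0, 3.0)),
        utility_weight=float(rng.normal(psa.utility_weight.mean, psa.utility_weight.sd)),
        n_prior_dmards=float(rng.normal(psa.n_prior_dmards.mean, psa.n_prior_dmards.sd)),
        disease_duration=float(rng.normal(psa.disease_duration.mean,
                                          psa.disease_duration.sd)),
        anti_ccp_positive=float(rng.normal(psa.anti_ccp_positive.mean,
                                           psa.anti_ccp_positive.sd)),
        anti_ccp_negative=float(rng.normal(psa.anti_ccp_negative.mean,
                                           psa.anti_ccp_negative.sd)),
    )


def _apply_draw(config: ModelConfig, draw: PSADraw) -> ModelConfig:
    cfg = config.model_copy(deep=True)
    months = cfg.settings.response_assessment_months
    for key, (a20, a50, a70) in draw.response.items():
        row = ResponseRow.model_construct(acr20=a20, acr50=a50, acr70=a70)
        if months == 6:
            cfg.response[key].m6 = row
        else:
            cfg.response[key].m3 = row
    cfg.mortality.rr_per_haq_unit = draw.mortality_rr
    cfg.population.mean_age = draw.age
    cfg.population.proportion_female = draw.proportion_female
    cfg.population.mean_weight_kg = draw.weight_kg
    cfg.population.baseline_haq = draw.baseline_haq
    cfg.utilities.baseline_utility = min(draw.utility_weight,
                                         cfg.utilities.utility_ceiling)
    # n_prior_dmards / disease_duration / anti-CCP enter only through the
    # (external) utility regression and are recorded but inert here
    cfg.population.n_prior_dmards = draw.n_prior_dmards
    cfg.population.disease_duration_years = draw.disease_duration
    return cfg


@dataclass
class PSAResult:
    """Per-draw incremental (Δcost, ΔQALY) pairs per comparison, seeded."""

    seed: int
    reference: str
    comparators: list[str]
    delta_cost: dict[str, np.ndarray]
    delta_qaly: dict[str, np.ndarray]
    ref_cost: np.ndarray = field(default_factory=lambda: np.empty(0))
    ref_qalys: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_draws(self) -> int:
        return len(self.ref_cost)

    def plane_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.comparators:
            rows.append(pd.DataFrame({
                "comparator": comp,
                "draw": np.arange(self.n_draws),
                "delta_cost": self.delta_cost[comp],
                "delta_qaly": self.delta_qaly[comp],
            }))
        return pd.concat(rows, ignore_index=True)


def run_psa(config: ModelConfig, strategies: list[str] | None = None,
            n_draws: int | None = None, seed: int = 0,
            reference: str = "CZP+MTX",
            life_table: LifeTable | None = None) -> PSAResult:
    """Monte-Carlo PSA: per draw, resolve the parameter sample, evaluate all
    strategies, and record incremental pairs against the reference.
    Reproducible under a fixed seed; weight draws feed weight-based dosing.
    """
    if n_draws is None:
        n_draws = config.psa.n_draws
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if strategies is None:
        strategies = [s.name for s in config.strategies if s.name != reference]
    life_table = life_table or make_synthetic_life_table()
    rng = np.random.default_rng(seed)
    dc = {c: np.empty(n_draws) for c in strategies}
    dq = {c: np.empty(n_draws) for c in strategies}
    ref_cost = np.empty(n_draws)
    ref_q = np.empty(n_draws)
    # independent log-odds draws routinely produce non-monotone cumulative
    # rows; the exclusive-category clamp handles them, so the per-draw
    # clamp warnings are suppressed here (they remain on for base runs)
    import warnings as _warnings
    engine_logger = logging.getLogger("racua.engine")
    old_level = engine_logger.level
    engine_logger.setLevel(logging.ERROR)
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            for i in range(n_draws):
                cfg = _apply_draw(config, sample_psa_draw(config, rng))
                ref_res = evaluate_strategy(cfg, reference, life_table)
                ref_cost[i], ref_q[i] = ref_res.cost, ref_res.qalys
                for comp in strategies:
                    res = evaluate_strategy(cfg, comp, life_table)
                    dc[comp][i] = ref_res.cost - res.cost
                    dq[comp][i] = ref_res.qalys - res.qalys
    finally:
        engine_logger.setLevel(old_level)
    return PSAResult(seed=seed, reference=reference, comparators=list(strategies),
                     delta_cost=dc, delta_qaly=dq, ref_cost=ref_cost, ref_qalys=ref_q)


def default_wtp_grid() -> np.ndarray:
    """€0–100,000 per QALY in €1,000 steps (the €30,000 threshold included)."""
    return np.arange(0.0, 100_001.0, 1000.0)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    λ, the fraction of draws in which the reference has positive net
    monetary benefit over the comparator (λ·ΔQALY − Δcost > 0)."""
    if psa.n_draws == 0:
        raise ValueError("PSA result holds no draws")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    rows = {"wtp": grid}
    for comp in psa.comparators:
        nmb = grid[:, None] * psa.delta_qaly[comp][None, :] - psa.delta_cost[comp][None, :]
        rows[comp] = (nmb > 0).mean(axis=1)
    return pd.DataFrame(rows)
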