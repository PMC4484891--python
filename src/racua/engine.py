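"""State space, transition matrices and cohort propagation.

The cohort enters on first-line biologic therapy; at the end of the
first cycle it is classified into exclusive ACR response categories
(non-responders move straight to the first conventional DMARD line).
Responders stay until discontinuation (constant hazard derived from the
37-month median biologic treatment duration) or death.  Each follow-up
line assesses response over its first cycle — non-responders move down
the sequence — and thereafter discontinues at its own median-duration
hazard.  The sequence ends in palliation; death is absorbing.

Mean HAQ-DI is tracked per state as a cohort "tracker" variable: flows
between states carry the origin state's mean HAQ plus a transition jump
(treatment gain, rebound), and states accrue within-cycle drift
(progression off biologic therapy, continuation improvement on it).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import ModelConfig, TreatmentStrategy
from .mortality import cycle_death_probabilities
from .synthetic import LifeTable, make_synthetic_life_table
from .utility import WEEKS_PER_MONTH, haq_to_utility_delta

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpace",
    "CohortTrace",
    "exclusive_response_probabilities",
    "median_to_cycle_discontinuation",
    "build_transition_matrix",
    "run_cohort",
    "cycle_grid",
]

_CATS = ("acr20", "acr50", "acr70")


def exclusive_response_probabilities(acr20: float, acr50: float, acr70: float
                                     ) -> tuple[float, float, float, float]:
    """Convert cumulative ACR response fractions to exclusive category
    probabilities (none, ACR20-only, ACR50-only, ACR70).

    Cumulative rows are consumed verbatim as printed; non-monotone inputs
    (which occur in the published table) are clamped to zero exclusive
    mass with a warning, and the probabilities always sum to 1.
    """
    for v in (acr20, acr50, acr70):
        if not (0.0 <= v <= 1.0):
            raise ValueError("cumulative fractions must lie in [0, 1]")
    if acr50 - acr70 < 0 or acr20 - acr50 < 0:
        warnings.warn(
            f"non-monotone cumulative ACR inputs ({acr20}, {acr50}, {acr70}): "
            "negative exclusive mass clamped to 0", stacklevel=2)
        logger.warning("clamped exclusive response mass for inputs (%s, %s, %s)",
                       acr20, acr50, acr70)
    # monotonize the cumulative row from the deepest category outward, then
    # take successive differences: conserves total mass under any input
    c70 = acr70
    c50 = max(acr50, c70)
    c20 = max(acr20, c50)
    return (1.0 - c20, c20 - c50, c50 - c70, c70)


def median_to_cycle_discontinuation(median_months: float, cycle_months: float) -> float:
    """Per-cycle discontinuation probability under a constant hazard with
    the given median time on treatment: 1 − 0.5^(cycle/median)."""
    if median_months <= 0 or cycle_months <= 0:
        raise ValueError("durations must be positive")
    return 1.0 - 0.5 ** (cycle_months / median_months)


class StateSpace:
    """Ordered state labels for one strategy's treatment sequence.

    entry, three first-line responder states, an (assessment, continuing)
    pair per conventional DMARD line, palliation, and an absorbing death
    state."""

    def __init__(self, strategy: TreatmentStrategy):
        self.lines = list(strategy.followup_sequence[:-1])
        names = ["entry", "acr20", "acr50", "acr70"]
        for line in self.lines:
            names += [f"{line}:assess", f"{line}:cont"]
        names += ["palliation", "death"]
        self.names: list[str] = names
        self.n = len(names)
        self.ENTRY = 0
        self.ACR = (1, 2, 3)
        self.PALLIATION = self.n - 2
        self.DEATH = self.n - 1

    def assess(self, k: int) -> int:
        return 4 + 2 * k

    def cont(self, k: int) -> int:
        return 5 + 2 * k

    def next_line_entry(self, k: int) -> int:
        """State entered on leaving line k (next assessment, or palliation)."""
        return self.assess(k + 1) if k + 1 < len(self.lines) else self.PALLIATION

    def index(self, name: str) -> int:
        return self.names.index(name)


def cycle_grid(config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """(start_months, length_months) of every cycle: the assessment cycle
    length repeats to month 12, then 6-month cycles to the horizon."""
    m = config.settings.response_assessment_months
    horizon_months = config.settings.horizon_years * 12.0
    lengths: list[float] = []
    t = 0.0
    while t < min(12.0, horizon_months) - 1e-9:
        lengths.append(float(m))
        t += m
    while t < horizon_months - 1e-9:
        step = min(float(config.settings.cycle_months_after_year1), horizon_months - t)
        lengths.append(step)
        t += step
    lengths_arr = np.array(lengths)
    starts = np.concatenate([[0.0], np.cumsum(lengths_arr)[:-1]])
    return starts, lengths_arr


@dataclass
class _StrategyParams:
    """Pre-resolved numeric inputs for one strategy's cohort run."""

    p_excl: tuple[float, float, float, float]       # none, 20only, 50only, 70
    delta_haq_first: np.ndarray                     # HAQ change per ACR state (<= 0)
    line_p_resp: np.ndarray                         # ACR20 response prob per line
    line_gain_haq: np.ndarray                       # conditional HAQ gain per line (>= 0)
    line_median_months: np.ndarray
    first_median_months: float


def _first_line_haq_deltas(config: ModelConfig) -> np.ndarray:
    """HAQ change for the three responder categories.  Explicit utility-gain
    overrides are converted back to HAQ equivalents through the mapping
    coefficient so that a single HAQ-anchored pathway drives utilities,
    mortality and band costs."""
    u = config.utilities
    if u.response_gain_override is not None:
        coef = u.bansback_coefficient
        return np.array([u.response_gain_override[c] / coef for c in _CATS])
    return np.array([config.haq_change_by_acr_category[c] for c in _CATS])


def _strategy_params(config: ModelConfig, strategy: TreatmentStrategy,
                     space: StateSpace) -> _StrategyParams:
    row = config.response[strategy.response_key].at_months(
        config.settings.response_assessment_months)
    p_excl = exclusive_response_probabilities(row.acr20, row.acr50, row.acr70)
    cats = config.haq_change_by_acr_category
    p_resp, gain, med = [], [], []
    for line in space.lines:
        fu = config.followup[line]
        r = fu.response_6mo
        pn, p20, p50, p70 = exclusive_response_probabilities(r.acr20, r.acr50, r.acr70)
        p_any = p20 + p50 + p70
        g = 0.0
        if p_any > 0:
            g = -(p20 * cats["acr20"] + p50 * cats["acr50"] + p70 * cats["acr70"]) / p_any
        p_resp.append(p_any)
        gain.append(g)
        med.append(fu.median_duration_months)
    return _StrategyParams(
        p_excl=p_excl,
        delta_haq_first=_first_line_haq_deltas(config),
        line_p_resp=np.array(p_resp),
        line_gain_haq=np.array(gain),
        line_median_months=np.array(med),
        first_median_months=strategy.median_duration_months,
    )


def _survivor_matrix(space: StateSpace, params: _StrategyParams,
                     first_cycle: bool, cycle_months: float) -> np.ndarray:
    """Transition matrix conditional on surviving the cycle (row-stochastic
    over living states; the death state row is identity)."""
    A = np.zeros((space.n, space.n))
    if first_cycle:
        pn, p20, p50, p70 = params.p_excl
        A[space.ENTRY, space.ACR[0]] = p20
        A[space.ENTRY, space.ACR[1]] = p50
        A[space.ENTRY, space.ACR[2]] = p70
        A[space.ENTRY, space.assess(0)] = pn
        for s in (*space.ACR, space.PALLIATION,
                  *(space.assess(k) for k in range(len(space.lines))),
                  *(space.cont(k) for k in range(len(space.lines)))):
            A[s, s] = 1.0
    else:
        A[space.ENTRY, space.ENTRY] = 1.0
        p_disc = median_to_cycle_discontinuation(params.first_median_months, cycle_months)
        for s in space.ACR:
            A[s, s] = 1.0 - p_disc
            A[s, space.assess(0)] = p_disc
        for k in range(len(space.lines)):
            nxt = space.next_line_entry(k)
            A[space.assess(k), space.cont(k)] = params.line_p_resp[k]
            A[space.assess(k), nxt] = 1.0 - params.line_p_resp[k]
            pk = median_to_cycle_discontinuation(params.line_median_months[k], cycle_months)
            A[space.cont(k), space.cont(k)] = 1.0 - pk
            A[space.cont(k), nxt] = pk
        A[space.PALLIATION, space.PALLIATION] = 1.0
    A[space.DEATH, space.DEATH] = 1.0
    return A


def _haq_jumps(space: StateSpace, params: _StrategyParams, first_cycle: bool,
               rebound_fraction: float, first_line_gain_haq: np.ndarray) -> np.ndarray:
    """HAQ increments carried by flows: treatment gain on classification or
    line response, rebound on discontinuation."""
    J = np.zeros((space.n, space.n))
    if first_cycle:
        for s, d in zip(space.ACR, params.delta_haq_first):
            J[space.ENTRY, s] = d
    else:
        for i, s in enumerate(space.ACR):
            J[s, space.assess(0)] = rebound_fraction * first_line_gain_haq[i]
        for k in range(len(space.lines)):
            J[space.assess(k), space.cont(k)] = -params.line_gain_haq[k]
            J[space.cont(k), space.next_line_entry(k)] = (
                rebound_fraction * params.line_gain_haq[k])
    return J


def build_transition_matrix(space: StateSpace, config: ModelConfig,
                            strategy: TreatmentStrategy, cycle_index: int,
                            haq_by_state: np.ndarray | None = None,
                            mean_age: float | None = None,
                            life_table: LifeTable | None = None) -> np.ndarray:
    """Full per-cycle transition matrix for audit: death applied first, then
    conditional transitions among survivors (rows sum to 1).

    When ``haq_by_state``/``mean_age`` are not given, baseline values at
    the cycle's start time are used.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    starts, lengths = cycle_grid(config)
    if cycle_index >= len(starts):
        raise ValueError("cycle_index beyond the model horizon")
    params = _strategy_params(config, strategy, space)
    life_table = life_table or make_synthetic_life_table()
    if haq_by_state is None:
        haq_by_state = np.full(space.n, config.population.baseline_haq)
    if mean_age is None:
        mean_age = config.population.mean_age + starts[cycle_index] / 12.0
    p_death = cycle_death_probabilities(
        mean_age, config.population.proportion_female, haq_by_state,
        lengths[cycle_index], config.mortality, life_table)
    p_death[space.DEATH] = 0.0
    A = _survivor_matrix(space, params, cycle_index == 0, lengths[cycle_index])
    M = A * (1.0 - p_death)[:, None]
    M[:, space.DEATH] += p_death
    if ((M < -1e-12) | (M > 1 + 1e-12)).any():
        raise ValueError("transition probabilities escaped [0, 1]")
    return M


@dataclass
class CohortTrace:
    """Per-cycle occupancy, mean HAQ and mean utility over the state space."""

    state_names: list[str]
    cycle_start_years: np.ndarray
    cycle_length_years: np.ndarray
    occupancy: np.ndarray          # (n_cycles, n_states)
    haq: np.ndarray                # (n_cycles, n_states), start-of-cycle means
    utility: np.ndarray            # (n_cycles, n_states); death = 0
    space: StateSpace

    def to_frame(self) -> pd.DataFrame:
        n_c, n_s = self.occupancy.shape
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(n_c), n_s),
            "time_years": np.repeat(self.cycle_start_years, n_s),
            "state": self.state_names * n_c,
            "occupancy": self.occupancy.ravel(),
            "mean_haq": self.haq.ravel(),
            "mean_utility": self.utility.ravel(),
        })


def run_cohort(config: ModelConfig, strategy: TreatmentStrategy,
               life_table: LifeTable | None = None) -> CohortTrace:
    """Propagate the cohort from unit mass in the entry state to the horizon.

    Occupancy is recorded at each cycle start; HAQ per state is the mean
    over occupants; utility is HAQ-anchored:
    u = baseline_utility + coefficient · (HAQ − baseline_HAQ), clipped to
    the configured floor/ceiling, zero in death.
    """
    space = StateSpace(strategy)
    params = _strategy_params(config, strategy, space)
    life_table = life_table or make_synthetic_life_table()
    starts_m, lengths_m = cycle_grid(config)
    n_cycles = len(starts_m)
    u = config.utilities
    pop = config.population

    occ = np.zeros((n_cycles, space.n))
    haq = np.zeros((n_cycles, space.n))
    occ_now = np.zeros(space.n)
    occ_now[space.ENTRY] = 1.0
    haq_now = np.full(space.n, pop.baseline_haq)
    # accumulated first-line HAQ gain per responder category (grows during
    # the continuation window, months 6-18)
    gain_first = -params.delta_haq_first.copy()

    # per-cycle drift rates (HAQ/year) by state
    drift = np.zeros(space.n)
    drift[list(space.ACR)] = u.haq_progression_on_biologic
    for k in range(len(space.lines)):
        drift[space.assess(k)] = u.haq_progression_conventional
        drift[space.cont(k)] = u.haq_progression_conventional
    drift[space.PALLIATION] = u.haq_progression_palliative

    matrix_cache: dict[tuple[bool, float], np.ndarray] = {}
    for c in range(n_cycles):
        occ[c] = occ_now
        haq[c] = haq_now
        dt_m = lengths_m[c]
        first = c == 0
        key = (first, dt_m)
        A = matrix_cache.get(key)
        if A is None:
            A = matrix_cache[key] = _survivor_matrix(space, params, first, dt_m)
        if c == n_cycles - 1:
            break
        p_death = cycle_death_probabilities(
            pop.mean_age + starts_m[c] / 12.0, pop.proportion_female,
            haq_now, dt_m, config.mortality, life_table)
        p_death[space.DEATH] = 0.0
        # end-of-cycle HAQ: within-cycle drift plus the continuation
        # improvement on first-line treatment over months 6-18
        haq_end = haq_now + drift * (dt_m / 12.0)
        t0, t1 = starts_m[c], starts_m[c] + dt_m
        overlap = max(0.0, min(t1, 18.0) - max(t0, 6.0)) / 12.0
        if overlap > 0:
            extra = u.continuation_gain_fraction * (-params.delta_haq_first) * overlap
            for i, s in enumerate(space.ACR):
                haq_end[s] -= extra[i]
                gain_first[i] += extra[i]
        haq_end = np.clip(haq_end, 0.0, u.haq_max)
        J = _haq_jumps(space, params, first, u.rebound_fraction, gain_first)
        surv = occ_now * (1.0 - p_death)
        F = surv[:, None] * A
        occ_next = F.sum(axis=0)
        occ_next[space.DEATH] += (occ_now * p_death).sum()
        mass_haq = (F * (haq_end[:, None] + J)).sum(axis=0)
        haq_next = haq_end.copy()
        live = occ_next > 1e-15
        live[space.DEATH] = False
        haq_next[live] = mass_haq[live] / occ_next[live]
        haq_next = np.clip(haq_next, 0.0, u.haq_max)
        occ_now, haq_now = occ_next, haq_next

    coef = u.bansback_coefficient
    utility = np.clip(u.baseline_utility + coef * (haq - pop.baseline_haq),
                      u.utility_floor, u.utility_ceiling)
    utility[:, space.DEATH] = 0.0
    return CohortTrace(
        state_names=space.names,
        cycle_start_years=starts_m / 12.0,
        cycle_length_years=lengths_m / 12.0,
        occupancy=occ,
        haq=haq,
        utility=utility,
        space=space,
    )
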