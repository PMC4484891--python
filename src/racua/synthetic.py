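"""Synthetic stand-ins for inputs the source analysis cites but does not print.

Four families of inputs fall in this category: the national age/sex life
table, the trial-population weight distribution, the baseline cohort
characteristics used for sampling, and the "defaults registry" of
second-line (conventional DMARD) efficacy, durations, HAQ-band resource
costs and response-category HAQ changes.  Everything here is labelled
with provenance "default", is deterministic or seed-reproducible, and is
overridable through the configuration tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import PopulationProfile, PSAInputs

__all__ = [
    "LifeTable",
    "WeightCDF",
    "DefaultsRegistry",
    "make_synthetic_life_table",
    "make_weight_cdf",
    "sample_baseline_cohort",
    "defaults_registry",
]

MAX_AGE = 100


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx by integer age and sex (ages 0..100).

    The probability at the terminal age (100) is 1 by construction.
    """

    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.qx_male, self.qx_female):
            if arr.shape != (MAX_AGE + 1,):
                raise ValueError("life table must cover ages 0..100")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("death probabilities must lie in [0, 1]")

    def annual_probability(self, age: int, sex: str) -> float:
        if not (0 <= age <= MAX_AGE):
            raise ValueError(f"age {age} outside life-table range 0..{MAX_AGE}")
        arr = self.qx_female if sex == "female" else self.qx_male
        return float(arr[age])

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(MAX_AGE + 1)
        return pd.DataFrame({
            "age": np.concatenate([ages, ages]),
            "sex": ["male"] * (MAX_AGE + 1) + ["female"] * (MAX_AGE + 1),
            "qx": np.concatenate([self.qx_male, self.qx_female]),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        male = df[df.sex == "male"].sort_values("age").qx.to_numpy(float)
        female = df[df.sex == "female"].sort_values("age").qx.to_numpy(float)
        return cls(qx_male=male, qx_female=female)


def make_synthetic_life_table(makeham_a: float = 1e-4,
                              gompertz_b: float = 4e-5,
                              gompertz_c: float = 0.098,
                              female_factor: float = 0.55) -> LifeTable:
    """Gompertz–Makeham life table: h(a) = A + B·exp(c·a), qx = 1 − exp(−h).

    Parameters roughly match Southern-European adult mortality; the female
    hazard is the male hazard scaled by ``female_factor``.  The terminal
    age (100) is forced to qx = 1.
    """
    if makeham_a < 0 or gompertz_b <= 0 or gompertz_c <= 0:
        raise ValueError("Makeham term must be >= 0, Gompertz terms > 0")
    if not (0 < female_factor <= 1):
        raise ValueError("female_factor must be in (0, 1]")
    ages = np.arange(MAX_AGE + 1, dtype=float)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    qx_m = 1.0 - np.exp(-hazard)
    qx_f = 1.0 - np.exp(-hazard * female_factor)
    qx_m[MAX_AGE] = 1.0
    qx_f[MAX_AGE] = 1.0
    return LifeTable(qx_male=qx_m, qx_female=qx_f)


@dataclass(frozen=True)
class WeightCDF:
    """Body-weight distribution with a log-normal shape.

    Parameterised by its median (kg) and a spread expressed as an
    absolute scale (kg) at the median, giving sigma = spread/median on
    the log scale.  Right-skewed with positive support, as weight data
    are; the median of the shipped default is the fixed 81.4 kg used for
    weight-based dosing.
    """

    median_kg: float
    sigma: float

    def cdf(self, w) :
        w = np.asarray(w, dtype=float)
        out = np.zeros_like(w)
        pos = w > 0
        out[pos] = stats.norm.cdf(np.log(w[pos] / self.median_kg) / self.sigma)
        return out if out.ndim else float(out)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        if ((u <= 0) | (u >= 1)).any():
            raise ValueError("quantile argument must lie in (0, 1)")
        out = self.median_kg * np.exp(self.sigma * stats.norm.ppf(u))
        return out if out.ndim else float(out)

    @property
    def mean_kg(self) -> float:
        return self.median_kg * math.exp(self.sigma ** 2 / 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.quantile(rng.uniform(size=n))


def make_weight_cdf(mean_kg: float = 81.4, spread: float = 15.0) -> WeightCDF:
    """Build the weight distribution; the default median is 81.4 kg."""
    if mean_kg <= 0 or spread <= 0:
        raise ValueError("weight parameters must be positive")
    return WeightCDF(median_kg=mean_kg, sigma=spread / mean_kg)


def sample_baseline_cohort(n: int, seed: int,
                           profile: PopulationProfile | None = None,
                           psa: PSAInputs | None = None) -> pd.DataFrame:
    """Sample per-subject baseline characteristics (age, sex, weight, HAQ,
    utility weight), reproducible under a fixed seed.

    Ages, HAQ and utility weights use the configured normal laws; sex is
    Bernoulli at the beta-mean female share n/N; weight comes from the
    log-normal weight distribution.  Marginal means converge to the
    profile means as n grows.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    profile = profile or PopulationProfile()
    psa = psa or PSAInputs()
    rng = np.random.default_rng(seed)
    a, b = psa.gender_beta_shapes
    p_female = a / (a + b)
    wcdf = make_weight_cdf(profile.mean_weight_kg, profile.weight_spread_kg)
    return pd.DataFrame({
        "age": rng.normal(psa.age.mean, psa.age.sd, size=n),
        "female": rng.uniform(size=n) < p_female,
        "weight_kg": wcdf.sample(n, rng),
        "haq": np.clip(rng.normal(psa.baseline_haq.mean, psa.baseline_haq.sd, size=n), 0, 3),
        "utility": rng.normal(psa.utility_weight.mean, psa.utility_weight.sd, size=n),
    })


@dataclass(frozen=True)
class DefaultsRegistry:
    """Documented synthetic defaults for unprinted model inputs.

    Every entry carries provenance "default" and a rationale string; none
    shadows a printed value.
    """

    followup_response_6mo: dict[str, dict[str, float]]
    followup_median_duration_months: dict[str, float]
    followup_daily_dose_mg: dict[str, float]
    discontinuation_efficacy_split: float
    haq_change_by_acr_category: dict[str, float]
    haq_band_costs: tuple[float, ...]
    continuation_gain_fraction: float
    haq_progression_conventional: float
    haq_progression_palliative: float
    rationale: dict[str, str] = field(default_factory=dict)
    provenance: str = "default"


def defaults_registry() -> DefaultsRegistry:
    """The shipped defaults registry.

    Construction constraints: second-line ACR20 at 6 months is strictly
    below the weakest printed biologic strategy (0.39, and well below the
    weakest printed combination, 0.482); efficacy decreases along the
    treatment sequence; HAQ-band costs are non-decreasing in disability;
    HAQ improvements are ordered by response depth with no change for
    non-responders.
    """
    seq_resp = {
        "sulfasalazine": dict(acr20=0.32, acr50=0.14, acr70=0.05),
        "leflunomide": dict(acr20=0.30, acr50=0.13, acr70=0.05),
        "gold sodium thiomalate": dict(acr20=0.26, acr50=0.11, acr70=0.04),
        "hydroxychloroquine": dict(acr20=0.24, acr50=0.10, acr70=0.03),
        "azathioprine": dict(acr20=0.22, acr50=0.09, acr70=0.03),
        "cyclosporine": dict(acr20=0.22, acr50=0.09, acr70=0.03),
        "penicillamine": dict(acr20=0.20, acr50=0.08, acr70=0.02),
    }
    durations = {
        "sulfasalazine": 26.0,
        "leflunomide": 24.0,
        "gold sodium thiomalate": 22.0,
        "hydroxychloroquine": 24.0,
        "azathioprine": 20.0,
        "cyclosporine": 20.0,
        "penicillamine": 18.0,
    }
    daily_dose = {
        "sulfasalazine": 2000.0,
        "leflunomide": 20.0,
        "gold sodium thiomalate": 50.0 / 7.0,  # 50 mg IM weekly
        "hydroxychloroquine": 400.0,
        "azathioprine": 200.0,    # ~2.5 mg/kg at the fixed 81.4 kg
        "cyclosporine": 250.0,    # ~3 mg/kg at the fixed 81.4 kg
        "penicillamine": 500.0,
    }
    rationale = {
        **{f"followup.{k}": "second-line conventional DMARD efficacy/duration not printed; "
                            "ordered weaker than every printed biologic row and decreasing "
                            "along the sequence" for k in seq_resp},
        "haq_change_by_acr_category": "trial repeated-measures HAQ changes not printed; "
                                      "magnitudes ordered by response depth",
        "haq_band_costs": "annual resource costs by HAQ band from the cited Swedish/UK "
                          "cohort are not printed; non-decreasing in disability",
        "discontinuation_efficacy_split": "split between lack-of-efficacy and adverse-event "
                                          "discontinuation is named but not quantified; both "
                                          "routes lead to the next line so the value is inert",
        "continuation_gain_fraction": "continued post-response improvement is described as "
                                      "'much smaller'; 10% of the first-cycle gain over "
                                      "months 6-18",
        "haq_progression": "annual HAQ worsening off biologic therapy; conventional slower "
                           "than palliative, biologic 0 as stated",
    }
    return DefaultsRegistry(
        followup_response_6mo=seq_resp,
        followup_median_duration_months=durations,
        followup_daily_dose_mg=daily_dose,
        discontinuation_efficacy_split=0.5,
        haq_change_by_acr_category={
            "none": 0.0, "acr20": -0.32, "acr50": -0.55, "acr70": -0.80,
        },
        haq_band_costs=(600.0, 1100.0, 2000.0, 3400.0, 5500.0, 8500.0),
        continuation_gain_fraction=0.1,
        haq_progression_conventional=0.045,
        haq_progression_palliative=0.06,
        rationale=rationale,
    )


def invert_cdf_by_bisection(cdf, u: float, lo: float = 1e-6, hi: float = 1e3) -> float:
    """Independent numerical quantile via bisection (testing oracle)."""
    return float(optimize.brentq(lambda w: cdf(w) - u, lo, hi, xtol=1e-10))
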