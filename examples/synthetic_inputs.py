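"""The synthetic stand-ins for unprinted inputs: life table, weight
distribution, baseline cohort sample and the defaults registry.

Prints a few representative values so the assumptions are inspectable:
annual death probabilities from the Gompertz-Makeham table, weight
quantiles around the fixed 81.4 kg dosing weight, and the second-line
DMARD efficacy defaults (deliberately weaker than every printed biologic
response row).
"""

from racua import (defaults_registry, make_synthetic_life_table,
                   make_weight_cdf, sample_baseline_cohort)

lt = make_synthetic_life_table()
print("annual death probability (male):",
      {a: round(lt.annual_probability(a, "male"), 5) for a in (40, 60, 80)})

w = make_weight_cdf()
print("weight quantiles (kg): 25%% %.1f  median %.1f  97.5%% %.1f"
      % (w.quantile(0.25), w.quantile(0.5), w.quantile(0.975)))

cohort = sample_baseline_cohort(n=10_000, seed=7)
print("sampled cohort: mean age %.1f, %.0f%% female, mean HAQ %.2f"
      % (cohort.age.mean(), 100 * cohort.female.mean(), cohort.haq.mean()))

reg = defaults_registry()
print("second-line ACR20 at 6 months:",
      {k: v["acr20"] for k, v in reg.followup_response_6mo.items()})
print("HAQ change by response category:", reg.haq_change_by_acr_category)
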