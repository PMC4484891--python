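# racua — cost-utility model for sequential rheumatoid-arthritis treatment

`racua` is a Markov cohort state-transition model, written for health
economists, that evaluates the lifetime cost-utility of first-line TNF
inhibitors for moderate-to-severe rheumatoid arthritis in the 2009
Spanish setting: certolizumab pegol (CZP), adalimumab (ADA), etanercept
(ETA) and infliximab (IFX), with or without methotrexate (MTX).  Patients
enter on a biologic, are classified at 3 or 6 months into ACR response
categories (none / ACR20 / ACR50 / ACR70), and non-responders or
discontinuers move through a sequence of conventional DMARDs
(sulfasalazine → leflunomide → gold → hydroxychloroquine → azathioprine →
cyclosporine → penicillamine) into palliation.  Death is absorbing.

## Model core

- **Cycles**: the response-assessment length (6 months in the base case,
  3 months as a scenario) to month 12, then 6-month cycles over a
  45-year horizon.
- **Effectiveness**: cumulative ACR response rates per strategy, converted
  to exclusive category probabilities `p70 = ACR70`, `p50 = ACR50 − ACR70`,
  `p20 = ACR20 − ACR50`, `p_none = 1 − ACR20` (non-monotone published rows
  are clamped with a warning).  Time on treatment follows a constant
  hazard calibrated to the 37-month median biologic duration,
  `p_disc = 1 − 0.5^(Δt/37)`.
- **Health effects**: mean HAQ-DI is tracked per state; utilities follow
  `ΔEQ-5D = −0.2102·ΔHAQ` from a pre-treatment utility of 0.38.
  First-cycle gains are front-loaded (80% by week 4), continue to grow
  slightly over months 6–18, and rebound fully (base case) on
  discontinuation; HAQ worsens on conventional and palliative therapy.
- **Mortality**: age/sex life-table hazards multiplied by `1.330^HAQ`
  (applied on the hazard scale).
- **Costs**: drug acquisition from explicit dosing schedules with per-unit
  wastage (weight-based IFX dosing at the fixed 81.4 kg cohort weight or
  integrated over a weight distribution), €232.80 per IV infusion,
  monitoring schedules, and HAQ-band annual disease costs; 3% inflation
  from the 2009 cost year and 3.5%/year discounting of costs and effects.
- **Analysis**: pairwise incremental costs/QALYs with dominance
  classification and ICERs (`ICER = Δcost/ΔQALY`, evaluated against a
  €30,000/QALY willingness-to-pay), registered one-way sensitivity
  scenarios, and a seeded probabilistic sensitivity analysis (1000 draws)
  with cost-effectiveness planes and acceptability curves.

Inputs the source evaluation uses but never prints — national life
tables, the trial weight distribution, second-line DMARD efficacy and
durations, HAQ-band costs, response-category HAQ changes — are supplied
by a documented synthetic defaults registry (`racua.synthetic`); every
configuration value carries a provenance flag (`"paper"` vs `"default"`).
Absolute cost/QALY totals therefore differ from the published ones, while
the arithmetic, structure and sensitivity machinery reproduce exactly.

## Worked example

```sh
python examples/base_case.py
```

```text
strategy                         cost (EUR)   QALYs  vs CZP+MTX
CZP+MTX                             154,615   5.347
ADA+MTX (every 2 weeks)             150,317   5.174  dC=+4,298 dQ=+0.173 ICER=24,777 EUR/QALY
ADA+MTX (weekly)                    192,959   5.174  dC=-38,344 dQ=+0.173 (reference_dominant)
ETA+MTX                             150,174   5.322  dC=+4,441 dQ=+0.025 ICER=176,211 EUR/QALY
IFX (3 mg/kg)+MTX                   144,188   5.010  dC=+10,427 dQ=+0.337 ICER=30,904 EUR/QALY
IFX (5 mg/kg)+MTX                   164,283   5.010  dC=-9,668 dQ=+0.337 (reference_dominant)
...
```

Each row is one first-line strategy's discounted mean lifetime cost and
QALYs under the default parameter set; the trailing columns compare it
with certolizumab pegol + methotrexate.  CZP+MTX dominates the weekly
adalimumab and 5 mg/kg infliximab combinations (cheaper and more
effective); against the remaining comparators the extra cost per QALY
gained is printed.  Further examples cover one-way sensitivity scenarios
(`examples/sensitivity_scenarios.py`), the probabilistic analysis with
CEAC output (`examples/probabilistic_analysis.py`) and the synthetic
input generators (`examples/synthetic_inputs.py`).

A thin CLI wraps the same library calls:

```sh
racua run-base-case --out out/
racua run-owsa --out out/ --scenarios horizon_5y,rebound_50
racua run-psa --out out/ --n-draws 1000 --seed 1
racua make-fixtures --out fixtures/
```

## Layout

```
src/racua/
  config.py     configuration types, defaults, provenance, scenarios
  synthetic.py  life table, weight CDF, cohort sampling, defaults registry
  mortality.py  HAQ-adjusted per-cycle death probabilities
  utility.py    utility/HAQ trajectories and QALY integration
  costs.py      dosing schedules, wastage, monitoring, discounting
  engine.py     state space, transition matrices, cohort propagation
  cea.py        incremental analysis, OWSA, PSA, CEAC
  cli.py        command-line entry points
docs/methods.md   modelling assumptions and numerical choices
examples/         narrative scripts, one per capability
```
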