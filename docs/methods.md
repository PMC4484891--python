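# Methods

## Model structure

The model is a cohort (not patient-level) state-transition system.  One
state space is built per first-line strategy: an entry state, three
first-line responder states (ACR20-only, ACR50-only, ACR70), an
(assessment, continuing) pair for each of the seven conventional DMARDs
in the follow-up sequence, a palliation state and an absorbing death
state — 20 states for the default sequence.

The entry cohort (mean age 52.165 years, 82.7% female, baseline HAQ-DI
1.624, utility 0.38) is classified at the end of the first cycle into
exclusive response categories derived from the cumulative ACR rows of
the configured response table.  Non-responders (no ACR20) move directly
to the first conventional line.  Responders keep their category for the
whole time on first-line treatment (no re-classification rule exists)
and leave through a constant discontinuation hazard calibrated to the
37-month median biologic duration, or through death.  Each follow-up
line assesses response over the first cycle spent on it — with 3-month
assessment cycles in year 1 this first line-cycle can be 3 months; its
response probability is still the line's 6-month ACR20, a deliberate
simplification — and thereafter discontinues at the hazard implied by
its own median duration.  Palliation exits only to death.

Competing risks within a cycle are composed sequentially: death first,
then discontinuation among survivors, so `stay = (1−p_death)(1−p_disc)`
and rows remain stochastic without renormalisation.  First-cycle deaths
are applied at the same step as response classification; because
everyone carries baseline HAQ during cycle 0, ordering is immaterial.
The cause of discontinuation (lack of efficacy vs adverse event) is
representable in configuration but inert: both routes lead to the same
next state, which a test asserts.

## HAQ tracking and utilities

Mean HAQ-DI is a per-state tracker variable.  Flows between states carry
the origin state's mean HAQ plus a transition jump; states accrue
within-cycle drift.  Jumps: entry → responder applies the category's
HAQ change (defaults 0 / −0.32 / −0.55 / −0.80, ordered by response
depth); discontinuation applies a rebound of `rebound_fraction` (base 1.0,
scenario 0.5) times the accumulated on-treatment gain — including the
continuation-phase improvement, so a 100% rebound returns the cohort
exactly to its pre-treatment trajectory; entering a follow-up line's
continuing state applies that line's response-conditional HAQ gain.
Drift: 0/year on biologics, 0.045/year on conventional DMARDs, 0.06/year
in palliation, all clamped to the instrument range [0, 3].  Because
follow-up states mix arrivals with different histories, their mean HAQ is
an occupancy-weighted average and the mortality multiplier is evaluated
at that mean (a standard cohort-level approximation, slightly convex-biased
via Jensen's inequality).

Utilities are HAQ-anchored everywhere:
`u = 0.38 − 0.2102·(HAQ − 1.624)`, clipped to [0, 1], zero in death.
Explicit regression-derived category gains can be supplied
(`response_gain_override`) and are converted to HAQ equivalents through
the same coefficient, keeping a single pathway for utilities, mortality
and HAQ-band costs; the "HAQ-DI as quality-of-life instrument" scenario
is therefore the identity under the defaults, and is kept as a
configuration flag for configurations that do supply EQ-5D-specific gains.

The first cycle integrates a piecewise-linear utility profile: 80% of
the category gain by week 4, the remainder linearly to cycle end.  Later
cycles use the start-of-cycle state mean (the shape is specified only for
the initial response period).  QALYs are occupancy-weighted utilities
times cycle length, discounted at 3.5%/year at cycle start (midpoint
under the optional half-cycle correction).

## Costs

Drug acquisition is computed from explicit dosing schedules on a weekly
grid (1 year = 52 weeks = 12 months for schedule arithmetic; cycle
windows are half-open).  Base-case costing is per unit dispensed —
unused drug in an opened vial/syringe is wasted — with the exact-dose
per-mg method as a scenario.  Weight-based infliximab dosing uses the
fixed 81.4 kg cohort weight in the base case; an expected-vial-count
integration over the weight distribution is available and collapses to
the fixed-weight result for a degenerate distribution.  Methotrexate
co-therapy costs zero in the base case (the configured pack price is
retained behind `mtx_cost_zero: false`).  IV strategies add €232.80 per
infusion; the IV-administration sensitivity scenarios pivot on the
€214.54 day-hospital figure (±20% → €257.45 / €171.63), both figures
appearing in the source tables.  Follow-up DMARDs are priced per-mg from
pack prices at documented daily doses under both costing methods —
tablet-level wastage is negligible and the pack-to-regimen conversion is
itself a default.  Monitoring (two rheumatologist visits and lab panels
per 6-month cycle, chest X-ray at baseline) is identical across biologic
strategies, so it cancels in incremental results.  Annual HAQ-band
disease costs are added from each state's current mean HAQ.  All costs
inflate at 3%/year from the 2009 cost year and discount at 3.5%/year
(net factor ≈ 0.99517/year); the combination rule (both factors at the
cycle-start offset) is a package choice, as no combination rule is
stated by the source.

The societal-perspective toggle exists but adds a zero default increment:
indirect costs are excluded from the model, so the scenario's cost
content is undefined and left as a configuration hook.

## Mortality

A Gompertz–Makeham life table (h(a) = 1e−4 + 4e−5·e^(0.098a), female
hazard scaled by 0.55, terminal age 100 forced to q = 1) stands in for
the national 2009 tables, which are not printed; parameters roughly match
Southern-European adult mortality and enter only as a background hazard.
The sex-weighted annual probability at the cohort's (integer-rounded)
current mean age is converted to a hazard, multiplied by `1.330^HAQ` on
the hazard scale (probability-scale multiplication could exceed 1 at high
ages), and converted to a cycle probability.  The cohort's mean age
advances by the cycle length each cycle.  Sex is a fixed mixture weight,
not separate traces — the minimal faithful reading of a single-cohort
model.

## Synthetic defaults

The defaults registry supplies everything cited but unprinted, each entry
flagged `provenance="default"` with a rationale: second-line ACR
responses (ACR20 0.20–0.32, strictly below the weakest printed biologic
row and decreasing along the sequence), second-line median durations
(18–26 months), HAQ-band annual costs (€600–€8,500, non-decreasing in
disability), response-category HAQ changes, a 10% continuation gain over
months 6–18, and HAQ progression rates.  The weight distribution is
log-normal with median 81.4 kg and sigma = spread/median (default spread
15 kg, so the mean sits ≈1.7% above the median); the median — the
quantity used for fixed-weight dosing — is the anchored value.  The
3-month adalimumab-combination response row lacks printed ACR50/70
values; they are imputed by scaling the strategy's 6-month category
ratios onto the printed 3-month ACR20.

What the synthetic inputs do *not* emulate: true national mortality
levels, the real second-line efficacy estimates, actual HAQ-band cost
magnitudes, or the trial ANACOVA utility regression (its covariates —
age, gender, baseline utility, disease duration, prior DMARDs, anti-CCP
status — are sampled in the PSA for completeness but affect nothing
without the regression; they are recorded as inert).  Passing tests
therefore demonstrate the correctness of the arithmetic, the transition
system, the discounting and the sensitivity machinery — not the absolute
published cost/QALY totals, which depend on those unprinted inputs.
Under the shipped defaults the dominance directions against the
comparators with component-wise weaker response rows reproduce the
published pattern; the etanercept comparison is genuinely sensitive to
the unprinted utility-gain inputs (its printed cumulative ACR50 exceeds
the reference's) and is reported rather than asserted.

## Probabilistic sensitivity analysis

1000 draws in the base configuration.  Per draw: response fractions are
perturbed independently on the log-odds scale (default SE 0.15, a
documented default — the network-meta-analysis CIs behind the published
PSA are unprinted) and re-converted through the clamping exclusive-
category transform; the mortality RR is lognormal with location ln 1.330
and scale (ln 1.610 − ln 1.099)/(2·1.96); gender is Beta(1506, 315);
weight is drawn from the weight distribution and feeds weight-based
dosing; age, baseline HAQ, utility weight and the inert regression
covariates are normal with SD = CI width/(2·1.96) (interval entries are
treated uniformly as 95% CIs).  Costs are held fixed — the published PSA
lists no cost distributions.  Everything is reproducible under a single
integer seed.  CEACs report, per willingness-to-pay value on a
€0–100,000 grid (€1,000 steps), the fraction of draws with positive net
monetary benefit `λ·ΔQALY − Δcost`.

## Numerical choices and problem sizes

Transition rows sum to 1 within 1e−12; occupancy conservation holds to
1e−9 over 90 cycles.  Discount accumulators match geometric closed forms
to 1e−10.  Non-monotone cumulative ACR rows are monotonized from the
deepest category outward before differencing, which conserves mass for
any input and leaves all printed rows unchanged; clamps are logged.
Utility-ceiling violations clamp with a warning.  The default analyses
run 90 cycles × 20 states per strategy evaluation (~10 ms); the shipped
tests run the full 1000-draw, all-strategy PSA (~3 minutes on one core).
Mean ages are rounded to integer years for life-table lookup; empty
states retain their last HAQ value (occupancy-weighted quantities ignore
them).

## Known limitations

- Cohort-mean HAQ per state, not a distribution: band costs and the
  mortality multiplier are evaluated at the mean.
- Follow-up lines carry one response level (their ACR20), not full
  category sub-states; no downstream quantity reported by the analysis
  uses finer granularity.
- No treatment re-challenge, no adverse-event costs, no indirect costs,
  no cause-specific mortality.
- The continuation-gain window is fixed to calendar months 6–18 from
  model start rather than per-patient time since response.
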