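"""One-way sensitivity analysis: re-run the incremental comparison under
registered scenario overrides (shorter horizon, partial rebound, per-mg
drug costing, mortality unlinked from disability).

Each row shows how the incremental result of certolizumab pegol + MTX
against one comparator moves when a single assumption changes — the ICER
is most sensitive to the time horizon, because drug costs concentrate
early while QALY gains accrue over a lifetime.
"""

from racua import default_parameter_set, make_synthetic_life_table, run_owsa

config = default_parameter_set()
life_table = make_synthetic_life_table()

table = run_owsa(
    config,
    scenarios=["horizon_5y", "horizon_10y", "rebound_50",
               "per_mg_costing", "mortality_off"],
    strategies=["ADA+MTX (every 2 weeks)", "IFX (3 mg/kg)+MTX"],
    life_table=life_table,
)

for _, row in table.iterrows():
    icer = f"{row.icer:,.0f}" if row.icer == row.icer and row.icer is not None \
        else row.dominance
    print(f"{row.scenario:16s} vs {row.comparator:26s} "
          f"dC={row.delta_cost:+10,.0f} dQ={row.delta_qaly:+.3f}  {icer}")
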