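"""Base-case cost-utility analysis: every first-line strategy versus
certolizumab pegol + methotrexate.

Builds the default (2009 Spanish) parameter set, runs the lifetime Markov
cohort model for each strategy, and prints discounted mean costs, QALYs
and the incremental comparison against the reference.  Negative Δcost
with positive ΔQALY means the reference strategy dominates (cheaper and
more effective); otherwise the ICER is the extra cost per QALY gained.
"""

from racua import (default_parameter_set, evaluate_strategy,
                   incremental_analysis, make_synthetic_life_table)

config = default_parameter_set()
life_table = make_synthetic_life_table()

results = {s.name: evaluate_strategy(config, s, life_table)
           for s in config.strategies}

ref = results["CZP+MTX"]
print(f"{'strategy':30s} {'cost (EUR)':>12s} {'QALYs':>7s}  vs CZP+MTX")
for name, res in results.items():
    line = f"{name:30s} {res.cost:12,.0f} {res.qalys:7.3f}"
    if name != ref.name:
        inc = incremental_analysis(ref, res)
        if inc.icer is not None:
            line += f"  dC={inc.delta_cost:+,.0f} dQ={inc.delta_qaly:+.3f} " \
                    f"ICER={inc.icer:,.0f} EUR/QALY"
        else:
            line += f"  dC={inc.delta_cost:+,.0f} dQ={inc.delta_qaly:+.3f} " \
                    f"({inc.dominance.value})"
    print(line)
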