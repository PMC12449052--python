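#!/usr/bin/env python
"""Electron bookkeeping and the H2 landscape of the competing sinks:
fermentation (H2 source), reductive acetogenesis and methanogenesis (H2
sinks), their acetate yields and dissolved-H2 thresholds.

Writes results/delta_g_sweep.tsv.
"""
import pandas as pd

from acetotype.thermo import (combine, delta_g_sweep, electron_balance,
                              h2_threshold, load_constants, pathway_yield)

reactions, cond = load_constants()
for name, rxn in reactions.items():
    print(f"{name}: {electron_balance(rxn):+d} reducing equivalents")
print(f"acetate yield: {pathway_yield('fermentation_only'):.0f} mol/mol glucose "
      f"(fermentation) vs {pathway_yield('fermentation_plus_wl'):.0f} "
      f"(fermentation + Wood-Ljungdahl)")
combined = combine("combined", reactions["glucose_fermentation"],
                   reactions["wl_acetogenesis"])
print(f"combined pathway net reducing equivalents: {electron_balance(combined)}")

rows = []
for name, rxn in reactions.items():
    if rxn.h2_exponent() == 0.0:
        continue
    for h2, dg in delta_g_sweep(rxn, cond, 1e-8, 1e-3):
        rows.append({"reaction": name, "dissolved_h2_M": h2,
                     "delta_g_kJ_per_mol": dg})
pd.DataFrame(rows).to_csv("results/delta_g_sweep.tsv", sep="\t", index=False)

t_ac = h2_threshold(reactions["wl_acetogenesis"], cond)
t_me = h2_threshold(reactions["hydrogenotrophic_methanogenesis"], cond)
print(f"dissolved-H2 threshold (ΔG=0) at rumen conditions: "
      f"acetogenesis {t_ac*1e6:.1f} uM vs methanogenesis {t_me*1e6:.2f} uM "
      f"(ratio {t_ac/t_me:.0f}x)")
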