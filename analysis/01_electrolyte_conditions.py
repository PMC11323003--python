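#!/usr/bin/env python
"""Electrolyte context of the membrane-DNA system.

Tabulates ionic strength, Bjerrum lengths and Debye screening for the
~50 mM MgCl₂ study condition in three media (water, the membrane
interior with ε_r = 40.1, bulk solution with ε_r = 92.2), and the Mg-Mg
coupling parameter Γ = l_B/d at the condensed-state interhelical
separations.  Writes results/electrolyte_conditions.csv and
results/coupling_parameters.csv.
"""

from pathlib import Path

import pandas as pd

from lipodna import electrolyte as el

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for label, eps, temp in [
    ("water_298K", 78.5, 298.0),
    ("lipid_eps40.1_300K", el.LIPID_EPSILON_R, 300.0),
    ("solution_eps92.2_300K", el.SOLUTION_EPSILON_R, 300.0),
]:
    cond = el.mgcl2(0.05, epsilon_r=eps, temperature=temp)
    rows.append({
        "medium": label,
        "epsilon_r": eps,
        "temperature_K": temp,
        "ionic_strength_M": el.ionic_strength(cond),
        "bjerrum_1e_nm": el.bjerrum_length(1.0, cond),
        "bjerrum_2e_nm": el.bjerrum_length(2.0, cond),
        "debye_length_nm": el.debye_length(cond),
    })
table = pd.DataFrame(rows)
table.to_csv(OUT / "electrolyte_conditions.csv", index=False)

couplings = []
for label, eps, d in [
    ("MgMg_lipid", el.LIPID_EPSILON_R, 2.97),
    ("MgMg_solution", el.SOLUTION_EPSILON_R, 2.89),
]:
    cond = el.mgcl2(0.05, epsilon_r=eps, temperature=300.0)
    couplings.append({
        "pair": label,
        "epsilon_r": eps,
        "separation_nm": d,
        "gamma": el.coupling_parameter(2, 2, d, cond),
    })
gdf = pd.DataFrame(couplings)
gdf.to_csv(OUT / "coupling_parameters.csv", index=False)

print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(gdf.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nFinding: 50 mM MgCl2 (I = 0.15 M) screens at ~0.79 nm (~8 A) in water. "
    "The reduced permittivity inside the membrane stack raises the divalent "
    "Bjerrum length to ~5.6 nm, putting confined Mg-Mg pairs at Gamma ~ 1.9 "
    "(strongly coupled) versus ~0.84 in solution (thermal)."
)
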