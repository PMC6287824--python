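"""Exact monoisotopic mass arithmetic for metabolite formulas.

Parses a few formulas, computes neutral and deprotonated-ion ([M-H]-)
masses, and shows the ppm error between an observed and a theoretical
ion mass — the unit everything downstream (alignment, networks) runs on.
"""

from mdinet import (default_building_blocks, deprotonated_ion_mass,
                    monoisotopic_mass, parse_formula, ppm_error)

for text in ["C5H7NO3", "C7H8O4S", "C20H32O2"]:
    f = parse_formula(text)
    print(f"{text:>10}  neutral {monoisotopic_mass(f):10.5f} Da   "
          f"[M-H]- {deprotonated_ion_mass(f):10.5f} Da")

arg = deprotonated_ion_mass(parse_formula("C6H14N4O2"))
print(f"\nobserved 173.104417 vs theoretical arginine ion {arg:.6f}: "
      f"{ppm_error(173.104417, arg):+.3f} ppm")

print("\nfirst building blocks (label, delta mass):")
for b in default_building_blocks()[:5]:
    print(f"  {b.label:>5}  {b.delta_mass:9.5f} Da  ({b.description})")
# The neutral-vs-ion difference is always one proton (1.0072765 Da); a
# sub-0.5 ppm match is what lets formulas propagate through the network.
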