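"""Liquid-handling arithmetic used to annotate screen wells.

The reverse-transfection protocol dispenses 20 ul of siRNA complex and
20 ul of cell suspension per 384-well; stimulation adds 10 ul of EGTA
stock to a 50 ul final volume.
"""

from notchscreen import cells_seeded, final_concentration

sirna = final_concentration(stock=50.0, added_vol=20.0, final_vol=40.0)
egta = final_concentration(stock=12.5, added_vol=10.0, final_vol=50.0)
cells = cells_seeded(density=35.0, volume=20.0)

print(f"final siRNA concentration : {sirna:.1f} nM")
print(f"final EGTA concentration  : {egta:.1f} mM")
print(f"cells seeded per well     : {cells:.0f}")
print()
print("Each well therefore receives 700 cells and a 25 nM knockdown dose;")
print("stimulated plates reach 2.5 mM EGTA, enough to destabilize the")
print("NOTCH1 heterodimerization domain and trigger receptor activation.")
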