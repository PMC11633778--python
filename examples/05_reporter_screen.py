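"""Viability-normalized reporter screen with the 30% modulation rule.

Luciferase output of the RBPJk reporter line is divided by the resazurin
viability readout, expressed as fold change against the plate's
non-targeting wells, and classified: fold <= 0.7 suppressor, >= 1.3
enhancer (boundaries inclusive).
"""

import dataclasses

import pandas as pd

from notchscreen import reporter as rp
from notchscreen import synthdata as sd

genes = [f"G{i}" for i in range(20)]
phen = {g: sd.NT_LIKE for g in genes}
phen["G0"] = dataclasses.replace(sd.NT_LIKE, signaling_mult=0.3)  # suppressor
phen["G1"] = dataclasses.replace(sd.NT_LIKE, signaling_mult=1.8)  # enhancer
phen["G2"] = dataclasses.replace(sd.NT_LIKE, signaling_mult=0.5, cell_count_mult=0.5)

frames = []
for i, cond in enumerate(("NoEGTA", "EGTA")):
    layout = sd.make_plate_layout(20, genes=genes, condition=cond, seed=2)
    frames.append(sd.simulate_reporter_plate(layout, phen, cv=0.1, seed=8 + i))
table = pd.concat(frames, ignore_index=True)

norm = rp.normalize_reporter(table)
window, window_ok = rp.assay_window(norm)
calls = rp.classify_signaling_table(norm)

print(f"EGTA assay window : {window:.1f}x (valid: {window_ok})")
for c in sorted(calls, key=lambda c: (c.gene, c.condition)):
    if c.direction != "none":
        print(f"  {c.gene} [{c.condition}]: fold {c.fold_change:.2f} -> {c.direction}")
print()
print("G2 halves both signaling and growth: dividing by viability removes")
print("the growth effect, so its fold change reflects signaling only.")
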