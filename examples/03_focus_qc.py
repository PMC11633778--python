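"""Out-of-focus field detection with Tukey boxplot statistics.

Per well, the coefficient of variation of the DAPI signal over each
(dilated) nucleus is pooled across the eight fields; the lower inner fence
LIF = Q1 - 1.5*IQR is estimated, and a field in which more than half of the
nuclei fall below the fence is excluded as out of focus.
"""

import numpy as np

import notchscreen as ns
from notchscreen import imaging as im
from notchscreen import synthdata as sd

rng = np.random.default_rng(3)
blurred = {1}  # plant one defocused field among eight
contrasts = {}
for f in range(8):
    fld = sd.render_field(
        sd.NT_LIKE,
        int(rng.poisson(12)),
        blur_sigma=4.0 if f in blurred else 0.0,
        seed=int(rng.integers(2**31)),
        shape=(160, 160),
        cell_radius_px=18.0,
    )
    img = im.correct_background(ns.FieldImage.from_synthetic(fld))
    nuclei = im.segment_nuclei(img.channels["DAPI"])
    contrasts[f] = im.field_nucleus_contrasts(img.channels["DAPI"], nuclei)

res = im.classify_fields_focus(contrasts)
print(f"well fence: Q1={res.q1:.3f}  Q3={res.q3:.3f}  LIF={res.lif:.3f}")
for f in range(8):
    mark = " <- excluded" if res.out_of_focus[f] else ""
    print(f"  field {f}: {len(res.contrasts[f]):2d} nuclei, "
          f"{100 * res.fraction_below_lif[f]:5.1f}% below LIF{mark}")
print()
print("The defocused field's nuclei lose edge contrast and drop below the")
print("fence, so the >50% rule removes exactly that field from analysis.")
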