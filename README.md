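# notchscreen

High-content RNAi screen analysis for NOTCH1 subcellular localization and
signaling in MCF10A cells.

Arrayed knockdown screens read out receptor trafficking phenotypes by
imaging: each 384-well plate carries one gene knockdown per well, eight
fields of view per well and three fluorescence channels (DAPI for nuclei,
phalloidin for cell cortices, and NOTCH1 immunofluorescence). This package
implements the full analysis chain for such a screen — and, because raw
screen images of this kind are rarely deposited, a synthetic-data module
that generates plates, field images with ground truth, and reporter-plate
readouts so every stage is testable end to end.

The pipeline stages are:

1. **Synthetic screen generation** (`notchscreen.synthdata`) — 384-well
   layouts with a media-filled outer ring and distributed controls
   (non-targeting, no-siRNA, PSENEN positive control, cytotoxic PLK1
   transfection control), rendered multi-channel fields with planted
   knockdown phenotypes, defocused fields, and luciferase/resazurin
   reporter tables. All outputs are deterministic given a seed.
2. **Image analysis** (`notchscreen.imaging`) — per-channel background
   correction (white top-hat), Otsu + distance-watershed nucleus
   segmentation, cell segmentation by nucleus-seeded watershed on the
   inverted phalloidin channel, derivation of nucleus / membrane-ring /
   cytosol compartments, per-cell exclusion flags (border, size,
   saturation, malformation), and out-of-focus field QC: per-nucleus DAPI
   contrast values are pooled per well, the lower inner fence
   `LIF = Q1 − 1.5·IQR` is estimated, and fields where more than 50% of
   nuclei fall below the LIF are excluded.
3. **Features** (`notchscreen.features`) — per-cell compartment
   intensities and Laplacian-of-Gaussian puncta counts, aggregated to the
   screen's per-well parameters: `QC1_NoOfAnalysedCells`, `N1_NucNotch`,
   `N3_MembNotch`, `N4_CellNotch`, `N5_PercentOfCellsWithSpots`,
   `N9_NoOfSpotsPerCell`.
4. **Hit calling** (`notchscreen.screenstats`) — per-plate robust
   z-scores, `z = (x − median) / (1.4826·MAD)`, computed over the sample
   wells of each plate and condition independently; a viability gate
   (strongly negative cell-count z or too few cells) that must catch the
   PLK1 controls; phenotypic classification of hits (increased
   intracellular, altered PM + intracellular, increased nuclear; wells
   with general loss of signal are reported but excluded); condition and
   screen-to-screen bookkeeping; Welch t tests with star labels.
5. **Reporter screen** (`notchscreen.reporter`) — luminescence divided by
   resazurin viability, fold change against the plate's non-targeting
   median (so the NT median fold is exactly 1), the inclusive ≥30%
   modulation rule, EGTA assay-window validation, and merging with
   localization hits.
6. **Colocalization** (`notchscreen.colocquant`) — ROI integrated
   densities (`%IntDens = 100 · ROI IntDens / whole-cell IntDens`) and
   ComDet-style puncta detection (intensity threshold 4) with greedy
   one-to-one colocalization at a 2-px maximum distance.

## Worked example

Simulate a 160-gene triplicate plate with five genes planted as a
spots-accumulation phenotype at three well-to-well SDs, then z-score and
call hits (`examples/04_hit_calling.py`):

```
genes screened : 160 (5 planted spots phenotypes)
hits called    : 5
  GENE001: increased_intracellular (N5=+3.9, N9=+2.3) [planted]
  GENE002: increased_intracellular (N5=+5.1, N9=+2.9) [planted]
  GENE003: increased_intracellular (N5=+4.0, N9=+3.0) [planted]
  GENE004: increased_intracellular (N5=+3.8, N9=+2.1) [planted]
  GENE005: increased_intracellular (N5=+4.1, N9=+3.1) [planted]
```

All five planted genes cross the |z| ≥ 2 threshold on the spot parameters
and are classified as increased intracellular NOTCH1; no inert gene is
called and the cytotoxic PLK1 controls are removed by the viability gate.
The other scripts in `examples/` walk through protocol arithmetic, field
rendering and segmentation, focus QC, the reporter screen and puncta
colocalization, each printing the numbers it computes.

A thin command line mirrors the stages for file-based runs:

```sh
notchscreen simulate --out-dir plate/ --seed 7
notchscreen features --in-dir plate/ --out features.csv
notchscreen hits --features features.csv --out-dir results/
notchscreen reporter --table plate/reporter.csv --out-dir results/
```

Outputs are CSV/JSON with the configuration hash embedded; `notchscreen
report` refuses to merge artifacts produced under different
configurations.

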