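# Methods

## Scope and model of the screen

The package analyzes an arrayed RNAi screen for NOTCH1 subcellular
localization: 384-well plates (16×24) whose outer ring of 76 wells is
media, with sample genes and controls shuffled over the 308 inner wells.
Each analyzed well contributes eight imaged fields with three channels —
DAPI (nuclei), phalloidin (cell cortices), NOTCH1 immunofluorescence —
and each gene is screened with and without EGTA stimulation (Ca²⁺
chelation that activates Notch cleavage); the two conditions are analyzed
independently throughout. The per-well readout is a six-parameter vector:
analyzed-cell count (QC1), mean nuclear / membrane / whole-cell NOTCH1
intensity (N1, N3, N4), and two spot parameters (N5, percentage of cells
with ≥ `spot_min` cytosolic puncta; N9, mean puncta per cell).

## Synthetic data generator

The generator is the package's substitute for undeposited raw screen
images, built to make every downstream stage testable against ground
truth.

**Field model.** Nucleus centroids are placed by dart throwing with a
minimum separation (relaxed stepwise in crowded fields, never below the
non-overlap bound); nuclei are random ellipses (semi-axes ≈ 4.5–8 px at
the default 7-px nucleus radius scale). Cell territories are the Voronoi
cells of the centroids clipped to a disk of `cell_radius_px` (default
22 px at 0.65 µm/px ≈ a 29-µm cell), which makes territories space-filling
where cells are dense and leaves genuine background elsewhere. Shared and
outer boundaries carry a ~2-px bright phalloidin ridge over a moderate
cytoplasmic phalloidin level, giving the inverted-phalloidin watershed a
well-posed problem. The per-cell NOTCH1 budget (lognormal, σ=0.15 around
2×10⁵ DN) is split between the membrane ring (per-cell inner erosion band
of `ring_width_px` = 3), the nucleus and the diffuse cytosol according to
the phenotype fractions, plus Poisson(`spot_rate`) Gaussian puncta (σ =
1.5 px, 8×10³ DN each) at random cytosol positions. Camera noise is
Poisson shot noise at unit gain plus Gaussian read noise (σ = 10 DN);
defocus is a Gaussian blur of recorded σ, flagged out-of-focus at σ ≥ 3.
Truth carries label images, spot coordinates, per-cell compartment signal
sums and the blur applied.

**Phenotypes.** A phenotype is (pm, cyto, nuc) signal fractions summing
to 1, a spot rate, a cell-count multiplier (viability) and a signaling
multiplier (reporter). The bundled classes are NT-like (0.55/0.30/0.15,
0.3 spots/cell), a PTPN23-like spots phenotype (spot rate 6), PSENEN-like
(NT localization, signaling ×0.2) and PLK1-like (cell count ×0.1). These
defaults are not claims about the real cell line; they are chosen so that
control behaviors the assay depends on (PLK1 wells must fail viability,
PSENEN wells must suppress the reporter) hold by construction.

**Feature-level simulator.** For plate-scale statistics
(`simulate_well_features`) wells are drawn directly at the feature level:
parameters are Gaussian around phenotype-implied means with configurable
well-to-well SDs (QC1 is Poisson, mean 200 cells/well). An effect planted
at k times a `WellNoise` SD is therefore exactly a k-sigma phenotype.
N5 is tied mechanistically to the spot rate as 100·P[Poisson(rate) ≥ 2],
so a spot-rate effect moves N5 and N9 together, as it would in images.
This simulator deliberately omits everything image-level — segmentation
error, focus loss, spatial plate effects — so hit-calling results on it
measure the statistics, not the imaging.

**What the generator does not emulate.** Illumination gradients (tested
separately as additive synthetic gradients), cell shape diversity,
texture, overlapping/mitotic cells, edge effects across a plate, spectral
bleed-through. Passing recovery tests on these synthetics shows the
algorithms are correct on well-posed inputs, not that real screen images
would segment this cleanly.

## Image analysis

**Background correction** is the white top-hat: a grey morphological
opening with a 101×101 separable kernel (radius 50, well above the
44-px cell diameter) is subtracted and the result clipped at zero. The
top-hat is idempotent, tracks smooth illumination gradients, and is
checked by comparing per-quadrant means of corrected(field + linear
gradient) against corrected(field) on the phalloidin channel. Limitation:
the min-filter background sits at the shot-noise floor, which scales with
local intensity; on dim channels a strong gradient therefore leaves a
small σ-dependent residual (~3.5σ differential) that subtraction cannot
remove.

**Nucleus segmentation**: Otsu threshold on the smoothed DAPI channel
(with a 3σ contrast guard so blank noisy fields yield no nuclei), hole
filling, distance-transform watershed from `peak_local_max` seeds
(min distance 7 px) to split touching nuclei, minimum area 40 px².

**Cell segmentation**: the phalloidin channel is tri-modal (background /
cytoplasm / ridge); the lower cut of a 3-class Otsu gives the foreground
candidate, closed and hole-filled (the threshold may capture only the
ridges; filling recovers the enclosed interiors), then eroded by 2 px at
the outer edge because the smoothed ridge bleeds past the true boundary
and would otherwise push the membrane ring off the cortex. Watershed
grows from the nucleus labels over the inverted-then-re-inverted channel
(lines settle on ridges); foreground never reached by a seed, and
everything below threshold, forms the excluded (cell-free) region. Each
cell is partitioned exactly into nucleus, membrane ring (erosion band of
`ring_width_px` = 3) and cytosol.

**Cell QC** flags border-touching cells, areas outside [200, 20000] px²,
cells with > 0.5% saturated pixels in DAPI or NOTCH1, and malformed cells
(no nucleus, or solidity < 0.8). Only passing cells enter features.

**Focus QC.** Per-nucleus contrast is the coefficient of variation of
DAPI over the nucleus dilated by 2 px (to include the sharp nuclear edge;
blur provably lowers it, and it is intensity-scale invariant — the exact
contrast statistic of the original instrument software is not
recoverable, so this is a documented convention, as is the fence).
Contrasts are pooled over all nuclei of a well; the lower inner fence is
Tukey's `Q1 − k·IQR` with k = 1.5 and linearly interpolated quantiles; a
field is excluded when strictly more than `min_frac` = 0.5 of its nuclei
fall below the fence. Fields with no nuclei are excluded; wells with
fewer than 4 nuclei get no fence (nothing excluded by contrast).

*Known limitation — contamination at the fence's breakdown point.* Q1 is
robust only to < 25% contamination. If blurred fields carry ≥ 25% of a
well's nuclei, Q1 falls inside the low-contrast cluster and the fence
collapses below every value, so nothing is flagged in that well. With
exactly 2 of 8 fields blurred the per-well contaminated fraction
fluctuates around 25% (Poisson cell counts), so roughly half the wells
sit past the breakdown: measured sensitivity over 50 such wells is ~0.4–
0.7 depending on seed, while specificity stays at 1.0. At ≤ 1 blurred
field of 8 (contamination ~12%) detection is essentially perfect. This is
a property of the quartile fence itself, not of the contrast metric or
noise level; no parameter within the documented convention (k = 1.5,
> 50% rule) removes it.

## Screen statistics

z-scores are computed per plate × condition as
`(x − median) / (1.4826·MAD)` over the plate's *sample wells* (with
thousands of mostly-inert genes this is the standard reference population
for arrayed screens; an NT-referenced or classic mean/SD variant is
selectable). MAD = 0 falls back to the SD with a warning. Replicates
(triplicate plates per condition) are combined as the mean of per-plate
z-scores — robust to a single bad plate — before gating and calling.

The viability gate excludes wells with `z_QC1 ≤ −2` or fewer than
`min_cells` = 50 analyzed cells; a run is valid only if every PLK1
control is gated. Hits require |z| ≥ `z_hit` (default 2; the original
screen printed no cutoff, so totals like a specific hit count are not
claimed reproducible) on a localization parameter in a non-gated well,
classified by rule: N5 or N9 up → increased intracellular, additionally
N3 down → altered PM + intracellular, N1 up alone → increased nuclear,
N4 down alone → decreased total (reported separately and excluded from
the hit list, mirroring the screen's treatment of general signal loss).
Excursion patterns matching none of these classes (e.g. N3 up alone) are
recorded with their driving z-scores but not called — the class
enumeration is closed, and a hit must have a phenotypic class.
Cross-screen confirmation requires a secondary (independent-reagent) hit
with the same class under the same condition.

## Reporter screen

`normalized = luminescence / viability` (the assay measures resazurin
precisely to discount proliferation effects; division makes the fold
change viability-invariant, which is tested), fold change against the
same-plate, same-condition non-targeting median (median, not mean, to
resist single bad control wells; NT median fold is exactly 1 by
construction). Classification uses the inclusive 30% rule: fold ≤ 0.7
suppressor, ≥ 1.3 enhancer. A plate pair is valid when the EGTA/NoEGTA
ratio of NT medians reaches `stim_factor_min` = 2 (inclusive). Raw
luminescence and viability are retained alongside the normalized values.

## Colocalization quantification

Puncta detection smooths at the particle scale (σ = size/4), takes local
maxima, and keeps candidates whose (peak − local median)/local robust
noise exceeds the intensity threshold (default 4) on **both** the raw and
the smoothed image — a raw noise spike fails the smoothed test and a
correlated noise bump fails the raw test, while a real punctum passes
both. The threshold is an SNR-like quantity in the spirit of the ComDet
plugin's documented semantics, not a claim of bit-compatibility.
Centroids are intensity-weighted within the particle window (subpixel).
Colocalization matches spots one-to-one greedily in increasing distance
order with a 2-px maximum; greedy matching is oracle-checked against
exhaustive maximum matching on small instances (it can differ on
contrived geometries, < 5% of random small cases). Counts are symmetric
in channel order; fractions are referenced to channel A. `%IntDens`
follows the ROI formula directly and is additive over partitions.
Replicate summaries are flagged valid at ≥ 5 ROIs from ≥ 5 images (both
inclusive).

## Numerical and interface choices

- All randomness flows from explicit per-call `numpy` Generators; the
  same seed reproduces layouts, images and tables byte for byte.
- Coordinates are 0-based row-major (row, col); `Spot.x` is the column.
- Quantiles use linear interpolation between order statistics.
- Star labels: ns ≥ 0.05 > * > ** > *** > **** (< 10⁻⁴); Welch test via
  `scipy.stats.ttest_ind(equal_var=False)`; two zero-variance samples
  with equal means return ns.
- Degenerate inputs: empty DAPI field → empty label image; empty
  compartment → intensity 0 with a warning; a nucleus outside every cell
  is dropped with a warning; viability ≤ 0 drops the reporter well.
- CSV outputs are UTF-8, comma-separated, with a `# config_hash=` header
  line; JSON outputs embed the hash; `report` refuses mixed hashes.

## Problem sizes used in the recovery studies

Segmentation recovery: 20 fields × ~30 cells at 256². Focus QC: 50 wells
× 8 fields (12 cells/field at 160²), 2 fields blurred at σ = 4. Hit
calling: 5 screens × 320 genes × 2 conditions-worth of triplicate plates
at the feature level. Reporter: 10 trials × 40 genes × 4 replicate
wells. Colocalization: 20 trials × 200 spots at 512². These sizes give
stable estimates (binomial SE ≲ 2% on the rates reported) while keeping
the full recomputation around a minute on one CPU.
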