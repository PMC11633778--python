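"""Field-image analysis: background correction, segmentation, cell QC and
out-of-focus field exclusion.

The pipeline mirrors a classic high-content screening script: per-channel
background correction, DAPI-based nucleus segmentation, cell segmentation by
watershed on the inverted phalloidin channel seeded at the nuclei (watershed
lines fall on the bright cortical ridges), derivation of nucleus / membrane
ring / cytosol compartments, per-cell exclusion flags, and a per-well focus
QC built on Tukey boxplot statistics of nuclear intensity contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "FieldImage",
    "SegmentationResult",
    "CellQCFlags",
    "FocusQCResult",
    "correct_background",
    "segment_nuclei",
    "segment_cells",
    "derive_compartments",
    "qc_cells",
    "nucleus_contrast",
    "lower_inner_fence",
    "classify_fields_focus",
    "segment_field",
]


@dataclass
class FieldImage:
    """One multi-channel field with acquisition annotations."""

    channels: dict[str, np.ndarray]
    bit_depth: int = 16
    pixel_size_um: float = 0.65
    well: str = ""
    field: int = 0
    barcode: str = ""
    condition: str = "NoEGTA"

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @classmethod
    def from_synthetic(cls, synth) -> "FieldImage":
        return cls(
            channels={k: v.copy() for k, v in synth.channels.items()},
            pixel_size_um=synth.pixel_size_um,
            well=synth.well,
            field=synth.field,
            barcode=synth.barcode,
            condition=synth.condition,
        )


@dataclass
class SegmentationResult:
    """Nucleus and cell label images plus derived compartment masks.

    ``compartments`` maps cell id -> {'nucleus', 'membrane_ring', 'cytosol'}
    boolean full-frame masks; the three masks partition the cell mask.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    excluded_region_mask: np.ndarray
    compartments: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def cell_ids(self) -> list[int]:
        ids = np.unique(self.cell_labels)
        return [int(i) for i in ids if i != 0]


@dataclass(frozen=True)
class CellQCFlags:
    border: bool = False
    too_small: bool = False
    too_big: bool = False
    saturated: bool = False
    malformed: bool = False

    @property
    def passed(self) -> bool:
        return not (
            self.border
            or self.too_small
            or self.too_big
            or self.saturated
            or self.malformed
        )


@dataclass
class FocusQCResult:
    """Per-well focus QC: Tukey fence over pooled nuclear contrasts."""

    contrasts: dict[int, np.ndarray]  # field -> per-nucleus contrasts
    q1: float
    q3: float
    lif: float
    fraction_below_lif: dict[int, float]
    out_of_focus: dict[int, bool]


# --------------------------------------------------------------------------
# background correction


def correct_background(
    image: FieldImage, method: str = "opening", radius: int = 50
) -> FieldImage:
    """Subtract a smooth per-channel background estimate, clipping at 0.

    ``opening`` uses a large-kernel grey morphological opening (the
    rolling-ball workalike); ``median`` a large median filter. Channels are
    corrected independently.
    """
    if method not in ("opening", "median"):
        raise ValueError(f"unknown background method {method!r}")
    out: dict[str, np.ndarray] = {}
    size = 2 * radius + 1  # separable square kernel: fast at large radii
    for name, ch in image.channels.items():
        arr = ch.astype(np.float64)
        if method == "opening":
            # white top-hat: subtracting the opening is idempotent and
            # tracks smooth illumination gradients
            bg = ndi.grey_opening(arr, size=(size, size))
        else:
            bg = ndi.median_filter(arr, size=size)
        corr = np.clip(arr - bg, 0.0, None)
        out[name] = corr
    return FieldImage(
        channels=out,
        bit_depth=image.bit_depth,
        pixel_size_um=image.pixel_size_um,
        well=image.well,
        field=image.field,
        barcode=image.barcode,
        condition=image.condition,
    )


# --------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    dapi: np.ndarray,
    *,
    min_nucleus_area: int = 40,
    smooth_sigma: float = 1.0,
    min_peak_distance: int = 7,
) -> np.ndarray:
    """Segment nuclei on the DAPI channel.

    Otsu threshold on the smoothed channel, hole filling, then a
    distance-transform watershed to split touching nuclei; objects below
    ``min_nucleus_area`` pixels are discarded. A blank field yields an
    empty label image.
    """
    arr = np.asarray(dapi, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("dapi must be a 2-D channel")
    sm = ndi.gaussian_filter(arr, smooth_sigma)
    if sm.max() <= sm.min():
        return np.zeros(arr.shape, dtype=np.int32)
    thr = threshold_otsu(sm)
    fg = sm > thr
    # Otsu on a blank-but-noisy field splits the noise; require real contrast
    if fg.any() and (sm[fg].mean() - sm[~fg].mean()) < 3.0 * sm[~fg].std():
        return np.zeros(arr.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    fg = ndi.binary_opening(fg, structure=disk(2))
    if not fg.any():
        return np.zeros(arr.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(arr.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)
    # drop small fragments, relabel consecutively
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_nucleus_area)
    keep = keep[keep != 0]
    remap = np.zeros(sizes.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def segment_cells(
    phalloidin: np.ndarray,
    nuclei: np.ndarray,
    *,
    smooth_sigma: float = 1.0,
    edge_trim_px: int = 2,
) -> SegmentationResult:
    """Cell segmentation by nucleus-seeded watershed on inverted phalloidin.

    The phalloidin channel is inverted so that cell interiors are bright and
    the cortical ridges dark; regions then grow from the nucleus seeds and
    watershed lines settle on the ridges. Pixels below the foreground
    threshold, and foreground regions that contain no nucleus seed, go to
    the excluded-region mask (image area not covered by cells).
    """
    phal = np.asarray(phalloidin, dtype=np.float64)
    if phal.shape != nuclei.shape:
        raise ValueError("phalloidin and nuclei shapes differ")
    sm = ndi.gaussian_filter(phal, smooth_sigma)
    if nuclei.max() == 0:
        return SegmentationResult(
            nucleus_labels=nuclei.astype(np.int32),
            cell_labels=np.zeros_like(nuclei, dtype=np.int32),
            excluded_region_mask=np.ones(nuclei.shape, dtype=bool),
        )
    # the phalloidin channel is tri-modal (background / cell interior /
    # cortical ridge): the lower multi-Otsu cut separates cells from the
    # uncovered background
    fg = np.ones(sm.shape, dtype=bool)
    trim = 0
    if sm.max() > sm.min():
        try:
            from skimage.filters import threshold_multiotsu

            lo = threshold_multiotsu(sm, classes=3)[0]
        except ValueError:  # too few distinct values
            lo = sm.min()
        cand = sm > lo
        # require real contrast, else treat the whole frame as covered
        if cand.any() and not cand.all():
            bg_vals = sm[~cand]
            if (sm[cand].mean() - bg_vals.mean()) > 3.0 * max(bg_vals.std(), 1e-9):
                fg = cand
                trim = edge_trim_px
    fg |= nuclei > 0
    # pad before the morphology so border handling cannot erode foreground
    # that touches the field edge; fill enclosed interiors (the threshold
    # may only capture the bright cortical ridges)
    padded = np.pad(fg, 4, mode="edge")
    padded = ndi.binary_closing(padded, structure=disk(2))
    padded = ndi.binary_fill_holes(padded)
    if trim > 0:
        # trim the outer foreground edge: the smoothed cortical ridge
        # bleeds past the true cell boundary and would push the membrane
        # ring off the cortex
        padded = ndi.binary_erosion(padded, structure=disk(trim))
    fg = padded[4:-4, 4:-4] | (nuclei > 0)

    inverted = sm.max() - sm  # interiors bright, ridges dark
    elevation = inverted.max() - inverted  # flood uphill toward ridges
    cells = watershed(elevation, markers=nuclei.astype(np.int32), mask=fg)
    # one cell per seeding nucleus; nothing grows without a seed, so any
    # foreground not reached stays excluded
    excluded = ~(cells > 0)
    return SegmentationResult(
        nucleus_labels=nuclei.astype(np.int32),
        cell_labels=cells.astype(np.int32),
        excluded_region_mask=excluded,
    )


def derive_compartments(
    seg: SegmentationResult, ring_width_px: int = 3
) -> SegmentationResult:
    """Split each cell into nucleus, membrane ring and cytosol masks.

    The membrane ring is the inner band of ``ring_width_px`` pixels along
    the cell boundary (erosion difference), the nucleus is the seeding
    nucleus clipped to the cell, and the cytosol is the remainder; the three
    masks partition the cell mask exactly. Nuclei falling outside any cell
    are dropped with a warning.
    """
    if ring_width_px < 0:
        raise ValueError("ring_width_px must be >= 0")
    cells = seg.cell_labels
    nuclei = seg.nucleus_labels
    compartments: dict[int, dict[str, np.ndarray]] = {}
    orphan = set()
    for nid in np.unique(nuclei):
        if nid == 0:
            continue
        owner = cells[nuclei == nid]
        if owner.max() == 0:
            orphan.add(int(nid))
    if orphan:
        logger.warning("dropping %d nuclei outside any cell", len(orphan))

    structure = disk(1)
    objects = ndi.find_objects(cells)
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        cell = cells[sl] == cid
        nuc = (nuclei[sl] > 0) & cell
        if ring_width_px > 0:
            interior = cell
            for _ in range(ring_width_px):
                interior = ndi.binary_erosion(interior, structure=structure)
            ring = cell & ~interior & ~nuc
        else:
            ring = np.zeros_like(cell)
        cyto = cell & ~nuc & ~ring

        def _full(m: np.ndarray) -> np.ndarray:
            out = np.zeros(cells.shape, dtype=bool)
            out[sl] = m
            return out

        compartments[cid] = {
            "nucleus": _full(nuc),
            "membrane_ring": _full(ring),
            "cytosol": _full(cyto),
        }
    seg.compartments = compartments
    return seg


def qc_cells(
    seg: SegmentationResult,
    image: FieldImage,
    min_area: int = 200,
    max_area: int = 20000,
    sat_frac: float = 0.005,
    *,
    min_solidity: float = 0.8,
    sat_channels: tuple[str, ...] = ("DAPI", "NOTCH1"),
) -> dict[int, CellQCFlags]:
    """Flag cells to exclude: border-touching, size outliers, saturated
    pixels, or malformed (no nucleus / low solidity) cells."""
    cells = seg.cell_labels
    h, w = cells.shape
    flags: dict[int, CellQCFlags] = {}
    border_ids = set(
        np.unique(
            np.concatenate(
                [cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]]
            )
        )
    )
    props = {p.label: p for p in regionprops(cells)}
    sat_value = image.max_value
    for cid in seg.cell_ids():
        p = props[cid]
        mask = cells == cid
        area = int(p.area)
        has_nucleus = bool((seg.nucleus_labels[mask] > 0).any())
        saturated = False
        for ch in sat_channels:
            if ch not in image.channels:
                continue
            vals = image.channels[ch][mask]
            if (vals >= sat_value).mean() > sat_frac:
                saturated = True
                break
        flags[cid] = CellQCFlags(
            border=cid in border_ids,
            too_small=area < min_area,
            too_big=area > max_area,
            saturated=saturated,
            malformed=(not has_nucleus) or (p.solidity < min_solidity),
        )
    return flags


# --------------------------------------------------------------------------
# focus QC


def nucleus_contrast(
    dapi: np.ndarray, nucleus_mask: np.ndarray, dilate_px: int = 2
) -> float:
    """Intensity contrast of one nucleus: coefficient of variation of the
    DAPI signal over the nucleus dilated by ``dilate_px`` (to include the
    sharp nuclear edge). Scale-invariant; defocus blur lowers it."""
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    region = ndi.binary_dilation(nucleus_mask, structure=disk(dilate_px))
    vals = np.asarray(dapi, dtype=np.float64)[region]
    mean = vals.mean()
    if mean == 0:
        return 0.0
    return float(vals.std() / mean)


def field_nucleus_contrasts(
    dapi: np.ndarray, nucleus_labels: np.ndarray, dilate_px: int = 2
) -> np.ndarray:
    """Per-nucleus contrast values for one field."""
    out = []
    for sl, nid in zip(
        ndi.find_objects(nucleus_labels), range(1, nucleus_labels.max() + 1)
    ):
        if sl is None:
            continue
        pad = 2 + dilate_px
        sl2 = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, n))
            for s, n in zip(sl, nucleus_labels.shape)
        )
        out.append(
            nucleus_contrast(
                dapi[sl2], nucleus_labels[sl2] == nid, dilate_px=dilate_px
            )
        )
    return np.asarray(out, dtype=np.float64)


def lower_inner_fence(
    values, k: float = 1.5
) -> tuple[float, float, float]:
    """Tukey boxplot statistics: (Q1, Q3, Q1 - k*IQR).

    Quantiles use linear interpolation between order statistics. Requires
    at least 4 values.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 4:
        raise ValueError("need at least 4 values for fence estimation")
    q1 = float(np.quantile(arr, 0.25))
    q3 = float(np.quantile(arr, 0.75))
    return q1, q3, q1 - k * (q3 - q1)


def classify_fields_focus(
    well_fields: dict[int, np.ndarray],
    min_frac: float = 0.5,
    k: float = 1.5,
) -> FocusQCResult:
    """Per-well out-of-focus field classification.

    The fence is computed over all nuclei of the well pooled across fields;
    a field is out of focus when strictly more than ``min_frac`` of its
    nuclei have contrast below the lower inner fence. Fields with no nuclei
    are counted as out of focus (they contribute no analyzable cells).
    """
    pooled = np.concatenate(
        [np.asarray(v, dtype=np.float64) for v in well_fields.values()]
    ) if well_fields else np.array([])
    if pooled.size < 4:
        # too few nuclei to estimate a fence (e.g. a cytotoxic well): no
        # contrast-based exclusion; empty fields are still flagged below
        q1 = q3 = lif = float("nan")
        logger.info("well has %d nuclei; focus fence not estimated", pooled.size)
    else:
        q1, q3, lif = lower_inner_fence(pooled, k=k)
    frac: dict[int, float] = {}
    oof: dict[int, bool] = {}
    for f, vals in well_fields.items():
        vals = np.asarray(vals, dtype=np.float64)
        if vals.size == 0:
            frac[f] = 1.0
            oof[f] = True
            logger.info("field %s has no nuclei; marked out of focus", f)
            continue
        frac[f] = float((vals < lif).mean())
        oof[f] = frac[f] > min_frac
    return FocusQCResult(
        contrasts={f: np.asarray(v) for f, v in well_fields.items()},
        q1=q1,
        q3=q3,
        lif=lif,
        fraction_below_lif=frac,
        out_of_focus=oof,
    )


# --------------------------------------------------------------------------
# convenience: full segmentation of one field


def segment_field(
    image: FieldImage,
    *,
    background: bool = True,
    ring_width_px: int = 3,
    **qc_kwargs,
) -> tuple[SegmentationResult, dict[int, CellQCFlags]]:
    """Run background correction, nucleus + cell segmentation, compartment
    derivation and cell QC on one field; returns (segmentation, flags)."""
    img = correct_background(image) if background else image
    nuclei = segment_nuclei(img.channels["DAPI"])
    seg = segment_cells(img.channels["phalloidin"], nuclei)
    seg = derive_compartments(seg, ring_width_px=ring_width_px)
    flags = qc_cells(seg, image, **qc_kwargs)
    return seg, flags
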