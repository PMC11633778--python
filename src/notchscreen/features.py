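"""Per-cell NOTCH1 features and per-well screen parameters.

Turns a segmented field into per-cell compartment intensities and spot
counts, and aggregates QC-passed cells of a well into the screen's named
parameters: QC1_NoOfAnalysedCells, N1_NucNotch, N3_MembNotch, N4_CellNotch,
N5_PercentOfCellsWithSpots and N9_NoOfSpotsPerCell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)

__all__ = [
    "Spot",
    "CellFeatures",
    "WellFeatures",
    "WELL_FEATURE_COLUMNS",
    "detect_spots",
    "measure_cell",
    "measure_field",
    "aggregate_well",
]

WELL_FEATURE_COLUMNS = [
    "QC1_NoOfAnalysedCells",
    "N1_NucNotch",
    "N3_MembNotch",
    "N4_CellNotch",
    "N5_PercentOfCellsWithSpots",
    "N9_NoOfSpotsPerCell",
]


@dataclass(frozen=True)
class Spot:
    """One detected punctum; x is the column and y the row coordinate."""

    x: float
    y: float
    intensity: float
    cell_id: int = 0


@dataclass(frozen=True)
class CellFeatures:
    cell_id: int
    nuc_intensity: float
    memb_intensity: float
    cyto_intensity: float
    cell_intensity: float
    n_spots: int
    has_spots: bool


@dataclass(frozen=True)
class WellFeatures:
    """The screen's per-well parameters; intensity and spot parameters are
    NaN when fewer than ``min_cells`` cells were analyzable."""

    QC1_NoOfAnalysedCells: int
    N1_NucNotch: float
    N3_MembNotch: float
    N4_CellNotch: float
    N5_PercentOfCellsWithSpots: float
    N9_NoOfSpotsPerCell: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in WELL_FEATURE_COLUMNS}


def detect_spots(
    notch: np.ndarray,
    region_mask: np.ndarray | None = None,
    snr_threshold: float = 5.0,
    spot_sigma_px: float = 1.5,
    *,
    min_distance: int = 2,
) -> list[Spot]:
    """Detect NOTCH1 puncta by Laplacian-of-Gaussian filtering.

    Local maxima of the scale-normalized LoG response at ``spot_sigma_px``
    are kept when (peak - local background) / local robust noise exceeds
    ``snr_threshold``; local background and noise are the median and scaled
    MAD in a surrounding window. Spots outside ``region_mask`` are dropped.
    """
    if spot_sigma_px <= 0:
        raise ValueError("spot_sigma_px must be > 0")
    arr = np.asarray(notch, dtype=np.float64)
    # scale-normalized negative LoG: bright blobs become positive peaks
    response = -(spot_sigma_px**2) * ndi.gaussian_laplace(arr, spot_sigma_px)
    peaks = peak_local_max(
        response,
        min_distance=min_distance,
        threshold_abs=1e-9,
        exclude_border=False,
    )
    win = int(max(6 * spot_sigma_px, 8))
    spots: list[Spot] = []
    for r, c in peaks:
        if region_mask is not None and not region_mask[r, c]:
            continue
        sl = (
            slice(max(r - win, 0), min(r + win + 1, arr.shape[0])),
            slice(max(c - win, 0), min(c + win + 1, arr.shape[1])),
        )
        local = arr[sl]
        bg = float(np.median(local))
        noise = 1.4826 * float(np.median(np.abs(local - bg)))
        noise = max(noise, 1e-9)
        if (arr[r, c] - bg) / noise >= snr_threshold:
            spots.append(Spot(x=float(c), y=float(r), intensity=float(arr[r, c])))
    return spots


def measure_cell(
    compartments: dict[str, np.ndarray],
    notch: np.ndarray,
    spots: list[Spot],
    cell_id: int,
    *,
    spot_min: int = 2,
) -> CellFeatures:
    """Mean NOTCH1 intensity per compartment plus the cytosolic spot count.

    A cell ``has_spots`` when at least ``spot_min`` puncta were counted in
    its cytosol. Empty compartments record intensity 0 with a warning.
    """
    arr = np.asarray(notch, dtype=np.float64)

    def _mean(mask: np.ndarray, name: str) -> float:
        n = int(mask.sum())
        if n == 0:
            logger.warning("cell %d has empty %s; intensity set to 0", cell_id, name)
            return 0.0
        return float(arr[mask].mean())

    nuc = compartments["nucleus"]
    ring = compartments["membrane_ring"]
    cyto = compartments["cytosol"]
    cell_mask = nuc | ring | cyto
    cyto_spots = [
        s
        for s in spots
        if s.cell_id == cell_id and cyto[int(round(s.y)), int(round(s.x))]
    ]
    n_spots = len(cyto_spots)
    return CellFeatures(
        cell_id=cell_id,
        nuc_intensity=_mean(nuc, "nucleus"),
        memb_intensity=_mean(ring, "membrane ring"),
        cyto_intensity=_mean(cyto, "cytosol"),
        cell_intensity=_mean(cell_mask, "cell"),
        n_spots=n_spots,
        has_spots=n_spots >= spot_min,
    )


def measure_field(
    seg,
    notch: np.ndarray,
    flags,
    *,
    snr_threshold: float = 5.0,
    spot_sigma_px: float = 1.5,
    spot_min: int = 2,
) -> list[CellFeatures]:
    """Measure every QC-passed cell of a segmented field."""
    cells = []
    all_cyto = np.zeros(seg.cell_labels.shape, dtype=bool)
    for comp in seg.compartments.values():
        all_cyto |= comp["cytosol"]
    spots = detect_spots(
        notch, all_cyto, snr_threshold=snr_threshold, spot_sigma_px=spot_sigma_px
    )
    spots = [
        Spot(
            s.x,
            s.y,
            s.intensity,
            cell_id=int(seg.cell_labels[int(round(s.y)), int(round(s.x))]),
        )
        for s in spots
    ]
    for cid, comp in seg.compartments.items():
        if cid in flags and not flags[cid].passed:
            continue
        cells.append(
            measure_cell(comp, notch, spots, cid, spot_min=spot_min)
        )
    return cells


def aggregate_well(
    cells: list[CellFeatures], min_cells: int = 50
) -> WellFeatures:
    """Aggregate QC-passed cells (from in-focus fields) to well parameters.

    QC1 is the analyzed-cell count; N1/N3/N4 are means of the compartment
    intensities; N5 is the percentage of cells with spots; N9 the mean spot
    count per cell. All but QC1 are NaN when the count is below
    ``min_cells``.
    """
    n = len(cells)
    if n == 0 or n < min_cells:
        return WellFeatures(n, math.nan, math.nan, math.nan, math.nan, math.nan)
    return WellFeatures(
        QC1_NoOfAnalysedCells=n,
        N1_NucNotch=float(np.mean([c.nuc_intensity for c in cells])),
        N3_MembNotch=float(np.mean([c.memb_intensity for c in cells])),
        N4_CellNotch=float(np.mean([c.cell_intensity for c in cells])),
        N5_PercentOfCellsWithSpots=100.0 * sum(c.has_spots for c in cells) / n,
        N9_NoOfSpotsPerCell=float(np.mean([c.n_spots for c in cells])),
    )


def well_features_frame(
    per_well: dict[str, WellFeatures], layout
) -> pd.DataFrame:
    """Assemble a features table in the screen CSV convention."""
    rows = []
    for well, wf in sorted(per_well.items()):
        role, gene = layout.wells[well]
        rows.append(
            dict(
                barcode=layout.barcode,
                well=well,
                condition=layout.condition,
                gene="" if gene is None else gene,
                role=role,
                replicate=layout.replicate,
                **wf.as_dict(),
            )
        )
    return pd.DataFrame(rows)
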