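"""End-to-end glue: from field images to per-well screen parameters.

One call per well runs background correction, segmentation, per-field
nuclear-contrast focus QC, cell QC and feature extraction, then aggregates
the QC-passed cells of the in-focus fields into the well parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .features import WellFeatures, aggregate_well, measure_field
from .imaging import (
    FieldImage,
    FocusQCResult,
    classify_fields_focus,
    field_nucleus_contrasts,
    segment_field,
)

logger = logging.getLogger(__name__)

__all__ = ["WellAnalysis", "analyze_well", "analyze_screen"]


@dataclass
class WellAnalysis:
    well: str
    features: WellFeatures
    focus: FocusQCResult
    n_fields: int
    n_fields_excluded: int
    n_cells_segmented: int
    n_cells_passed: int
    segmentations: dict = field(default_factory=dict)


def analyze_well(
    fields: dict[int, FieldImage],
    config: RunConfig | None = None,
    *,
    keep_segmentations: bool = False,
) -> WellAnalysis:
    """Analyze all fields of one well and aggregate to well parameters."""
    cfg = config or RunConfig()
    segs: dict[int, tuple] = {}
    contrasts: dict[int, object] = {}
    for f, img in fields.items():
        seg, flags = segment_field(
            img,
            ring_width_px=cfg.ring_width_px,
            min_area=cfg.min_cell_area,
            max_area=cfg.max_cell_area,
            sat_frac=cfg.sat_frac,
            min_solidity=cfg.min_solidity,
        )
        segs[f] = (seg, flags, img)
        contrasts[f] = field_nucleus_contrasts(
            img.channels["DAPI"], seg.nucleus_labels
        )
    focus = classify_fields_focus(
        contrasts, min_frac=cfg.focus_min_frac, k=cfg.fence_k
    )
    cells = []
    n_seg = 0
    n_passed = 0
    for f, (seg, flags, img) in segs.items():
        n_seg += len(flags)
        if focus.out_of_focus[f]:
            continue
        measured = measure_field(
            seg,
            img.channels["NOTCH1"].astype(float),
            flags,
            snr_threshold=cfg.snr_threshold,
            spot_sigma_px=cfg.spot_sigma_px,
            spot_min=cfg.spot_min,
        )
        n_passed += len(measured)
        cells.extend(measured)
    wf = aggregate_well(cells, min_cells=cfg.min_cells)
    well = next(iter(fields.values())).well if fields else ""
    n_excluded = sum(focus.out_of_focus.values())
    logger.info(
        "well %s: %d fields (%d excluded by focus QC), %d cells segmented, %d passed",
        well,
        len(fields),
        n_excluded,
        n_seg,
        n_passed,
    )
    return WellAnalysis(
        well=well,
        features=wf,
        focus=focus,
        n_fields=len(fields),
        n_fields_excluded=n_excluded,
        n_cells_segmented=n_seg,
        n_cells_passed=n_passed,
        segmentations=segs if keep_segmentations else {},
    )


def analyze_screen(
    fields_by_well: dict[str, dict[int, FieldImage]],
    layout,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Analyze every well of a plate; returns the per-well features table."""
    from .features import well_features_frame

    per_well = {}
    for well, fields in sorted(fields_by_well.items()):
        per_well[well] = analyze_well(fields, config).features
    return well_features_frame(per_well, layout)
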