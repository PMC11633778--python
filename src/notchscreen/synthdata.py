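"""Synthetic 384-well screen data with ground truth.

Emulates the primary-screen raw material: plate layouts with control wells
and a media-filled outer ring, three-channel field images (DAPI nuclei,
phalloidin cell cortices, NOTCH1 immunofluorescence) with known phenotypes
planted per gene, out-of-focus fields, luciferase/resazurin reporter plates,
and the liquid-handling arithmetic used to annotate wells.

Every operation takes an explicit seed and owns its random generator; the
same seed reproduces layouts, images and tables bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "PhenotypeSpec",
    "PlateLayout",
    "SyntheticField",
    "ProtocolParams",
    "NT_LIKE",
    "SPOTS_LIKE",
    "PSENEN_LIKE",
    "PLK1_LIKE",
    "ROLE_SAMPLE",
    "ROLE_NT",
    "ROLE_NO_SIRNA",
    "ROLE_POS_CTRL",
    "ROLE_TRANSFECTION_CTRL",
    "ROLE_MEDIA",
    "well_name",
    "border_wells",
    "make_plate_layout",
    "render_field",
    "simulate_screen",
    "simulate_reporter_plate",
    "simulate_well_features",
    "final_concentration",
    "cells_seeded",
]

N_ROWS, N_COLS = 16, 24
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

ROLE_SAMPLE = "sample"
ROLE_NT = "NT"
ROLE_NO_SIRNA = "no_siRNA"
ROLE_POS_CTRL = "pos_ctrl_PSENEN"
ROLE_TRANSFECTION_CTRL = "transfection_ctrl_PLK1"
ROLE_MEDIA = "media"

CONDITIONS = ("NoEGTA", "EGTA")


# --------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class PhenotypeSpec:
    """Planted knockdown phenotype for one gene (or control role).

    ``pm_frac``/``cyto_frac``/``nuc_frac`` apportion the per-cell NOTCH1
    signal between the membrane ring, the diffuse cytosol and the nucleus
    and must sum to 1. ``spot_rate`` is the Poisson mean of intracellular
    NOTCH1 puncta per cell. ``cell_count_mult`` scales the expected number
    of cells per well (a viability effect) and ``signaling_mult`` scales
    reporter output.
    """

    pm_frac: float
    cyto_frac: float
    nuc_frac: float
    spot_rate: float = 0.0
    cell_count_mult: float = 1.0
    signaling_mult: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        fracs = (self.pm_frac, self.cyto_frac, self.nuc_frac)
        if any(f < 0 for f in fracs):
            raise ValueError("compartment fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"compartment fractions must sum to 1, got {sum(fracs)!r}"
            )
        if self.spot_rate < 0:
            raise ValueError("spot_rate must be >= 0")
        if self.cell_count_mult <= 0 or self.signaling_mult <= 0:
            raise ValueError("multipliers must be > 0")


#: Non-targeting control: mostly cell-surface NOTCH1, few puncta.
NT_LIKE = PhenotypeSpec(0.55, 0.30, 0.15, spot_rate=0.3, label="NT-like")
#: Endosomal-trapping knockdown: strong intracellular puncta accumulation.
SPOTS_LIKE = PhenotypeSpec(
    0.25, 0.55, 0.20, spot_rate=6.0, label="PTPN23-like spots"
)
#: gamma-secretase-deficient positive control: localization like NT but
#: strongly reduced reporter signaling.
PSENEN_LIKE = dataclasses.replace(
    NT_LIKE, signaling_mult=0.2, label="PSENEN-like"
)
#: Cytotoxic transfection control.
PLK1_LIKE = dataclasses.replace(
    NT_LIKE, cell_count_mult=0.1, label="PLK1-like toxic"
)


# --------------------------------------------------------------------------
# plate layout


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> well id such as ``'B03'``."""
    return f"{ROW_LETTERS[row]}{col + 1:02d}"


def border_wells() -> list[str]:
    """All wells on the outer ring of the 16x24 plate (media wells)."""
    out = []
    for r in range(N_ROWS):
        for c in range(N_COLS):
            if r in (0, N_ROWS - 1) or c in (0, N_COLS - 1):
                out.append(well_name(r, c))
    return out


@dataclass
class PlateLayout:
    """384-well plate map: well -> (role, gene), plus plate metadata."""

    barcode: str
    condition: str
    replicate: int
    wells: dict[str, tuple[str, str | None]]  # well -> (role, gene or None)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(self.wells) != N_ROWS * N_COLS:
            raise ValueError("layout must cover all 384 wells")
        for w in border_wells():
            if self.wells[w][0] != ROLE_MEDIA:
                raise ValueError(f"outer well {w} must be media")
        genes = [g for r, g in self.wells.values() if r == ROLE_SAMPLE]
        if len(genes) != len(set(genes)):
            raise ValueError("a gene may occupy at most one sample well")

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, (r, _) in self.wells.items() if r == role)

    @property
    def sample_genes(self) -> list[str]:
        return [self.wells[w][1] for w in self.wells_with_role(ROLE_SAMPLE)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in sorted(self.wells):
            role, gene = self.wells[w]
            rows.append(
                dict(
                    well=w,
                    row=ROW_LETTERS.index(w[0]),
                    col=int(w[1:]) - 1,
                    role=role,
                    gene="" if gene is None else gene,
                    condition=self.condition,
                    barcode=self.barcode,
                    replicate=self.replicate,
                )
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        wells = {
            r.well: (r.role, r.gene if r.gene else None)
            for r in df.itertuples()
        }
        first = df.iloc[0]
        return cls(
            barcode=str(first.barcode),
            condition=str(first.condition),
            replicate=int(first.replicate),
            wells=wells,
        )


DEFAULT_CONTROL_COUNTS = {
    ROLE_NT: 8,
    ROLE_POS_CTRL: 4,
    ROLE_TRANSFECTION_CTRL: 4,
    ROLE_NO_SIRNA: 4,
}


def make_plate_layout(
    n_sample_wells: int,
    control_counts: dict[str, int] | None = None,
    condition: str = "NoEGTA",
    seed: int = 0,
    *,
    genes: list[str] | None = None,
    barcode: str = "PLATE01",
    replicate: int = 1,
) -> PlateLayout:
    """Lay out one 384-well screen plate.

    The outer ring (76 wells) is media. Sample and control wells are placed
    on the 320 inner wells by a seeded shuffle, as on the screen plates
    where controls were distributed across the plate.
    """
    counts = dict(DEFAULT_CONTROL_COUNTS)
    if control_counts is not None:
        counts.update(control_counts)
    ring = border_wells()
    inner = [
        well_name(r, c)
        for r in range(1, N_ROWS - 1)
        for c in range(1, N_COLS - 1)
    ]
    n_controls = sum(counts.values())
    if n_sample_wells + n_controls > len(inner):
        raise ValueError(
            f"capacity exceeded: {n_sample_wells} sample + {n_controls} "
            f"control wells > {len(inner)} inner wells"
        )
    if genes is None:
        genes = [f"GENE{i + 1:04d}" for i in range(n_sample_wells)]
    if len(genes) != n_sample_wells:
        raise ValueError("len(genes) must equal n_sample_wells")

    rng = np.random.default_rng(seed)
    order = list(inner)
    rng.shuffle(order)

    wells: dict[str, tuple[str, str | None]] = {w: (ROLE_MEDIA, None) for w in ring}
    it = iter(order)
    for role, n in counts.items():
        for _ in range(n):
            wells[next(it)] = (role, None)
    for g in genes:
        wells[next(it)] = (ROLE_SAMPLE, g)
    for w in it:
        wells[w] = (ROLE_MEDIA, None)  # unused inner wells filled with media

    return PlateLayout(
        barcode=barcode, condition=condition, replicate=replicate, wells=wells
    )


# --------------------------------------------------------------------------
# field rendering


@dataclass
class FieldTruth:
    """Ground truth for a rendered field."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    spots: list[tuple[float, float, int]]  # (x=col, y=row, cell_id)
    compartment_sums: dict[int, dict[str, float]]
    blur_sigma: float
    is_out_of_focus: bool
    membrane_ring: np.ndarray | None = None


@dataclass
class SyntheticField:
    """3-channel rendered field image plus its ground truth."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    truth: FieldTruth
    well: str = ""
    field: int = 0
    barcode: str = ""
    condition: str = "NoEGTA"

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class NoiseParams:
    """Camera model: Poisson shot noise at unit gain plus Gaussian read noise."""

    gain: float = 1.0
    read_sigma: float = 10.0


def _place_nuclei(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_cells: int,
    min_sep: float,
) -> np.ndarray:
    """Dart-throwing placement of nucleus centroids with minimum separation."""
    pts: list[tuple[float, float]] = []
    margin = 10.0
    sep = min_sep
    while True:
        for _ in range(8000):
            if len(pts) == n_cells:
                break
            cand = (
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            )
            if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) >= sep for p in pts):
                pts.append(cand)
        if len(pts) == n_cells or sep <= 0.65 * min_sep:
            break
        # field is crowded: relax the separation a little and keep packing,
        # but never let nuclei overlap
        sep = max(0.85 * sep, 0.65 * min_sep)
    if len(pts) < n_cells:
        raise ValueError(
            f"could not place {n_cells} nuclei at separation {sep:.1f} in {shape}"
        )
    return np.asarray(pts, dtype=float)


def render_field(
    phenotype: PhenotypeSpec,
    n_cells: int,
    noise: NoiseParams | None = None,
    blur_sigma: float = 0.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.65,
    ring_width_px: int = 3,
    cell_radius_px: float = 22.0,
    nucleus_radius_px: float = 7.0,
    total_notch_per_cell: float = 2.0e5,
    spot_total_signal: float = 8.0e3,
    spot_sigma_px: float = 1.5,
    oof_sigma_threshold: float = 3.0,
) -> SyntheticField:
    """Render one field of view with ground truth.

    Cells are Voronoi territories around non-overlapping elliptical nuclei,
    clipped to a disk of ``cell_radius_px`` around each nucleus; shared and
    outer cell boundaries carry a bright 2-px phalloidin ridge, giving the
    inverted-phalloidin watershed a well-posed problem. The per-cell NOTCH1
    budget (lognormal around ``total_notch_per_cell``) is split between
    membrane ring, cytosol and nucleus according to the phenotype fractions;
    Poisson(``spot_rate``) Gaussian puncta are added in the cytosol.
    ``blur_sigma`` > 0 applies a Gaussian defocus blur to all channels and
    is recorded in the truth.
    """
    if noise is None:
        noise = NoiseParams()
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if shape[0] < 128 or shape[1] < 128:
        raise ValueError("image size must be at least 128x128")
    rng = np.random.default_rng(seed)
    h, w = shape

    dapi = np.full(shape, 100.0)
    phal = np.full(shape, 60.0)
    notch = np.full(shape, 40.0)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    spots: list[tuple[float, float, int]] = []
    comp_sums: dict[int, dict[str, float]] = {}

    if n_cells > 0:
        min_sep = max(2.6 * nucleus_radius_px, 1.2 * cell_radius_px)
        centroids = _place_nuclei(rng, shape, n_cells, min_sep)
        rr, cc = np.mgrid[0:h, 0:w]

        # Voronoi cell territories clipped to a disk around each nucleus
        tree = cKDTree(centroids)
        dist, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
        dist = dist.reshape(shape)
        vor = (idx.reshape(shape) + 1).astype(np.int32)
        cell_labels = np.where(dist <= cell_radius_px, vor, 0)

        # elliptical nuclei
        for i, (cy, cx) in enumerate(centroids, start=1):
            a = nucleus_radius_px * rng.uniform(0.85, 1.15)
            b = nucleus_radius_px * rng.uniform(0.65, 0.95)
            theta = rng.uniform(0, np.pi)
            dy, dx = rr - cy, cc - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            e = (u / a) ** 2 + (v / b) ** 2
            inside = (e <= 1.0) & (cell_labels == i)
            nucleus_labels[inside] = i
            dapi[inside] += 2500.0 * (1.0 - 0.3 * e[inside])

        # boundary ridge: foreground pixels adjacent to a different label
        fg = cell_labels > 0
        ridge = np.zeros(shape, dtype=bool)
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb = np.roll(cell_labels, shift, axis=ax)
            ridge |= fg & (nb != cell_labels)
        from scipy.ndimage import binary_dilation, distance_transform_edt

        ridge = binary_dilation(ridge) & fg  # ~2 px wide cortex
        phal[fg] += 250.0
        phal[ridge] += 2200.0

        # membrane ring: per-cell inner band of ring_width_px pixels along
        # the cell boundary (the erosion-band definition the analysis uses)
        ring_mask = np.zeros(shape, dtype=bool)
        for i in range(1, n_cells + 1):
            m = cell_labels == i
            ring_mask |= m & (distance_transform_edt(m) <= ring_width_px)

        for i in range(1, n_cells + 1):
            cell = cell_labels == i
            nuc = nucleus_labels == i
            ring = ring_mask & cell & ~nuc
            cyto = cell & ~nuc & ~ring
            total = total_notch_per_cell * rng.lognormal(0.0, 0.15)
            sums = {"membrane": 0.0, "cytosol": 0.0, "nucleus": 0.0}
            for mask, frac, key in (
                (ring, phenotype.pm_frac, "membrane"),
                (cyto, phenotype.cyto_frac, "cytosol"),
                (nuc, phenotype.nuc_frac, "nucleus"),
            ):
                n_px = int(mask.sum())
                if n_px and frac > 0:
                    notch[mask] += frac * total / n_px
                    sums[key] += frac * total
            # intracellular puncta in the cytosol
            k = rng.poisson(phenotype.spot_rate)
            cyto_idx = np.flatnonzero(cyto.ravel())
            for _ in range(int(k)):
                if cyto_idx.size == 0:
                    break
                pos = np.unravel_index(rng.choice(cyto_idx), shape)
                sy, sx = float(pos[0]), float(pos[1])
                dy, dx = rr - sy, cc - sx
                g = np.exp(-(dy**2 + dx**2) / (2 * spot_sigma_px**2))
                g *= spot_total_signal / (2 * np.pi * spot_sigma_px**2)
                added = np.where(cell, g, 0.0)
                notch += added
                sums["cytosol"] += float(added.sum())
                spots.append((sx, sy, i))
            comp_sums[i] = sums

    channels = {"DAPI": dapi, "phalloidin": phal, "NOTCH1": notch}
    if blur_sigma > 0:
        channels = {
            k: gaussian_filter(v, blur_sigma) for k, v in channels.items()
        }
    out: dict[str, np.ndarray] = {}
    for k, v in channels.items():
        img = rng.poisson(np.clip(v, 0, None) * noise.gain) / max(noise.gain, 1e-12)
        img = img + rng.normal(0.0, noise.read_sigma, size=v.shape)
        out[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = FieldTruth(
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        spots=spots,
        compartment_sums=comp_sums,
        blur_sigma=blur_sigma,
        is_out_of_focus=blur_sigma >= oof_sigma_threshold,
        membrane_ring=(
            (ring_mask & (nucleus_labels == 0)) if n_cells > 0 else None
        ),
    )
    return SyntheticField(channels=out, pixel_size_um=pixel_size_um, truth=truth)


ROLE_PHENOTYPES = {
    ROLE_NT: NT_LIKE,
    ROLE_NO_SIRNA: NT_LIKE,
    ROLE_POS_CTRL: PSENEN_LIKE,
    ROLE_TRANSFECTION_CTRL: PLK1_LIKE,
}


def _phenotype_for(
    role: str,
    gene: str | None,
    phenotype_map: dict[str, PhenotypeSpec],
    default: PhenotypeSpec | None,
) -> PhenotypeSpec | None:
    if role == ROLE_MEDIA:
        return None
    if role == ROLE_SAMPLE:
        if gene in phenotype_map:
            return phenotype_map[gene]
        if default is None:
            raise KeyError(f"no phenotype for gene {gene!r} and no default")
        return default
    return ROLE_PHENOTYPES[role]


def simulate_screen(
    layout: PlateLayout,
    phenotype_map: dict[str, PhenotypeSpec] | None = None,
    fields_per_well: int = 8,
    seed: int = 0,
    *,
    default_phenotype: PhenotypeSpec | None = NT_LIKE,
    mean_cells_per_field: float = 25.0,
    oof_fraction: float = 0.0,
    oof_sigma_range: tuple[float, float] = (3.0, 6.0),
    wells: list[str] | None = None,
    **render_kwargs,
) -> dict[tuple[str, int], SyntheticField]:
    """Render every non-media well of a plate, 8 fields per well by default.

    Per-field cell counts are Poisson around ``mean_cells_per_field`` scaled
    by the phenotype's ``cell_count_mult``; a fraction ``oof_fraction`` of
    fields is rendered defocused with a blur sigma drawn from
    ``oof_sigma_range``.
    """
    if phenotype_map is None:
        phenotype_map = {}
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], SyntheticField] = {}
    todo = wells if wells is not None else sorted(layout.wells)
    for well in todo:
        role, gene = layout.wells[well]
        ph = _phenotype_for(role, gene, phenotype_map, default_phenotype)
        if ph is None:
            continue
        for f in range(fields_per_well):
            blur = 0.0
            if oof_fraction > 0 and rng.random() < oof_fraction:
                blur = rng.uniform(*oof_sigma_range)
            n = int(rng.poisson(mean_cells_per_field * ph.cell_count_mult))
            fld = render_field(
                ph,
                n,
                blur_sigma=blur,
                seed=int(rng.integers(0, 2**31 - 1)),
                **render_kwargs,
            )
            fld.well, fld.field = well, f
            fld.barcode, fld.condition = layout.barcode, layout.condition
            out[(well, f)] = fld
    return out


# --------------------------------------------------------------------------
# reporter plate simulation


def simulate_reporter_plate(
    layout: PlateLayout,
    phenotype_map: dict[str, PhenotypeSpec] | None = None,
    cv: float = 0.1,
    seed: int = 0,
    *,
    default_phenotype: PhenotypeSpec | None = NT_LIKE,
    base_luminescence: float = 1.0e4,
    base_viability: float = 1.0e4,
    stimulation_factor: float = 5.0,
) -> pd.DataFrame:
    """Simulate the luciferase + resazurin readout of one reporter plate.

    Luminescence scales with the phenotype's ``signaling_mult`` times
    ``cell_count_mult`` (fewer cells produce less light), viability
    fluorescence with ``cell_count_mult`` alone; EGTA plates get the
    stimulation factor on luminescence. Both readouts carry lognormal noise
    of coefficient of variation ``cv``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if phenotype_map is None:
        phenotype_map = {}
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    stim = stimulation_factor if layout.condition == "EGTA" else 1.0

    def _ln() -> float:
        if sigma == 0:
            return 1.0
        return float(rng.lognormal(-0.5 * sigma**2, sigma))

    rows = []
    for well in sorted(layout.wells):
        role, gene = layout.wells[well]
        ph = _phenotype_for(role, gene, phenotype_map, default_phenotype)
        if ph is None:
            continue
        lum = base_luminescence * stim * ph.signaling_mult * ph.cell_count_mult * _ln()
        viab = base_viability * ph.cell_count_mult * _ln()
        rows.append(
            dict(
                barcode=layout.barcode,
                well=well,
                condition=layout.condition,
                gene="" if gene is None else gene,
                role=role,
                luminescence=lum,
                viability=viab,
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# feature-level well simulation (plate-scale hit-calling studies)


@dataclass(frozen=True)
class WellNoise:
    """Well-to-well SDs of the per-well parameters, in feature units."""

    sd_n1: float = 4.0
    sd_n3: float = 6.0
    sd_n4: float = 3.0
    sd_n5: float = 3.0
    sd_n9: float = 0.15


def phenotype_feature_means(
    ph: PhenotypeSpec,
    *,
    cell_mean_intensity: float = 120.0,
    mean_cells_per_well: float = 200.0,
) -> dict[str, float]:
    """Expected per-well parameter values implied by a phenotype."""
    n5 = 100.0 * (1.0 - math.exp(-ph.spot_rate) * (1.0 + ph.spot_rate))
    return {
        "QC1_NoOfAnalysedCells": mean_cells_per_well * ph.cell_count_mult,
        "N1_NucNotch": cell_mean_intensity * (0.5 + 2.0 * ph.nuc_frac),
        "N3_MembNotch": cell_mean_intensity * (0.5 + 3.0 * ph.pm_frac),
        "N4_CellNotch": cell_mean_intensity,
        "N5_PercentOfCellsWithSpots": n5,  # P[Poisson(rate) >= 2]
        "N9_NoOfSpotsPerCell": ph.spot_rate,
    }


def simulate_well_features(
    layout: PlateLayout,
    phenotype_map: dict[str, PhenotypeSpec] | None = None,
    seed: int = 0,
    *,
    default_phenotype: PhenotypeSpec | None = NT_LIKE,
    noise: WellNoise | None = None,
    mean_cells_per_well: float = 200.0,
) -> pd.DataFrame:
    """Draw a per-well feature table directly, without rendering images.

    The statistical twin of render+measure for plate-scale studies: per-well
    parameters are Gaussian around the phenotype-implied means with
    well-to-well SDs from ``noise`` (QC1 is Poisson). Planting an effect of
    k times a ``WellNoise`` SD therefore produces a k-sigma phenotype by
    construction.
    """
    if phenotype_map is None:
        phenotype_map = {}
    if noise is None:
        noise = WellNoise()
    rng = np.random.default_rng(seed)
    rows = []
    for well in sorted(layout.wells):
        role, gene = layout.wells[well]
        ph = _phenotype_for(role, gene, phenotype_map, default_phenotype)
        if ph is None:
            continue
        mu = phenotype_feature_means(
            ph, mean_cells_per_well=mean_cells_per_well
        )
        qc1 = int(rng.poisson(mu["QC1_NoOfAnalysedCells"]))
        rows.append(
            dict(
                barcode=layout.barcode,
                well=well,
                condition=layout.condition,
                gene="" if gene is None else gene,
                role=role,
                replicate=layout.replicate,
                QC1_NoOfAnalysedCells=qc1,
                N1_NucNotch=mu["N1_NucNotch"] + rng.normal(0, noise.sd_n1),
                N3_MembNotch=mu["N3_MembNotch"] + rng.normal(0, noise.sd_n3),
                N4_CellNotch=mu["N4_CellNotch"] + rng.normal(0, noise.sd_n4),
                N5_PercentOfCellsWithSpots=float(
                    np.clip(
                        mu["N5_PercentOfCellsWithSpots"]
                        + rng.normal(0, noise.sd_n5),
                        0.0,
                        100.0,
                    )
                ),
                N9_NoOfSpotsPerCell=max(
                    0.0, mu["N9_NoOfSpotsPerCell"] + rng.normal(0, noise.sd_n9)
                ),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# protocol arithmetic


@dataclass(frozen=True)
class ProtocolParams:
    """Liquid-handling constants of the reverse-transfection protocol."""

    sirna_stock_nM: float = 50.0
    complex_vol_ul: float = 20.0
    cell_vol_ul: float = 20.0
    cell_density_per_ul: float = 35.0
    egta_stock_mM: float = 12.5
    egta_add_vol_ul: float = 10.0
    final_well_vol_ul: float = 50.0

    def __post_init__(self) -> None:
        if any(
            v <= 0
            for v in (
                self.sirna_stock_nM,
                self.complex_vol_ul,
                self.cell_vol_ul,
                self.cell_density_per_ul,
                self.egta_stock_mM,
                self.egta_add_vol_ul,
                self.final_well_vol_ul,
            )
        ):
            raise ValueError("all protocol parameters must be > 0")


def final_concentration(stock: float, added_vol: float, final_vol: float) -> float:
    """Concentration after diluting ``added_vol`` of ``stock`` into ``final_vol``."""
    if added_vol <= 0 or final_vol <= 0:
        raise ValueError("volumes must be > 0")
    if added_vol > final_vol:
        raise ValueError("added_vol must not exceed final_vol")
    return stock * added_vol / final_vol


def cells_seeded(density: float, volume: float) -> float:
    """Number of cells dispensed at ``density`` cells/volume-unit in ``volume``."""
    if density < 0:
        raise ValueError("density must be >= 0")
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return density * volume
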