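"""Plate-level screen statistics: robust z-scores, viability gating,
localization hit calling with phenotypic classification, cross-condition
and cross-screen bookkeeping, and the two-sample t-test star labels.

z-scores are computed per plate and per condition against the sample-well
population (robust median/MAD center and scale by default), the standard
choice for arrayed RNAi screens where most genes are inert; the stimulated
(EGTA) plates are analyzed independently of the unstimulated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import WELL_FEATURE_COLUMNS
from .synthdata import ROLE_SAMPLE, ROLE_TRANSFECTION_CTRL

logger = logging.getLogger(__name__)

__all__ = [
    "LOCALIZATION_PARAMS",
    "ZScoreTable",
    "HitCall",
    "ScreenTally",
    "plate_zscores",
    "average_replicate_zscores",
    "viability_gate",
    "call_hits",
    "combine_conditions",
    "reconcile_screens",
    "percentage",
    "ttest_stars",
]

#: Localization parameters entering the hit rule (QC1 drives viability only).
LOCALIZATION_PARAMS = [
    "N1_NucNotch",
    "N3_MembNotch",
    "N4_CellNotch",
    "N5_PercentOfCellsWithSpots",
    "N9_NoOfSpotsPerCell",
]

_MAD_SCALE = 1.4826  # MAD -> SD for a normal distribution


@dataclass
class ZScoreTable:
    """Per-well z-scores plus the per-plate reference statistics."""

    table: pd.DataFrame  # well rows with z_* columns
    reference: pd.DataFrame  # (barcode, condition, parameter) -> center, scale


@dataclass(frozen=True)
class HitCall:
    gene: str
    condition: str
    hit: bool
    phenotypic_class: str  # increased_intracellular | altered_PM_and_intracellular
    # | increased_nuclear | decreased_total | none
    driving: dict = field(default_factory=dict, hash=False, compare=False)
    viability_excluded: bool = False


@dataclass
class ScreenTally:
    n_screened: int = 0
    n_primary_hits: int = 0
    n_only_NoEGTA: int = 0
    n_only_EGTA: int = 0
    n_both: int = 0
    n_secondary_reproduced: int = 0
    class_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_primary_hits": self.n_primary_hits,
            "n_only_NoEGTA": self.n_only_NoEGTA,
            "n_only_EGTA": self.n_only_EGTA,
            "n_both": self.n_both,
            "n_secondary_reproduced": self.n_secondary_reproduced,
            "class_counts": dict(self.class_counts),
        }


def _robust_center_scale(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    scale = _MAD_SCALE * mad
    if scale == 0:
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        logger.warning("MAD is 0; falling back to SD = %g", sd)
        scale = sd
    return med, scale


def plate_zscores(
    features: pd.DataFrame,
    method: str = "robust",
    *,
    min_reference_wells: int = 8,
    reference_role: str = ROLE_SAMPLE,
) -> ZScoreTable:
    """z-score the well parameters of one or more plates.

    Each (barcode, condition) plate is standardized separately. The
    reference population is the plate's sample wells; ``robust`` uses
    median and 1.4826*MAD, ``classic`` mean and SD. Wells whose feature is
    undefined (NaN) get no z-score.
    """
    if method not in ("robust", "classic"):
        raise ValueError(f"unknown z-score method {method!r}")
    out = features.copy()
    ref_rows = []
    for col in WELL_FEATURE_COLUMNS:
        out[f"z_{col}"] = np.nan
    for (barcode, condition), grp in features.groupby(["barcode", "condition"]):
        ref = grp[grp["role"] == reference_role]
        for col in WELL_FEATURE_COLUMNS:
            vals = ref[col].dropna().to_numpy(dtype=float)
            if vals.size < min_reference_wells:
                raise ValueError(
                    f"plate {barcode}/{condition}: only {vals.size} reference "
                    f"wells with defined {col} (< {min_reference_wells})"
                )
            if method == "robust":
                center, scale = _robust_center_scale(vals)
            else:
                center = float(np.mean(vals))
                scale = float(np.std(vals, ddof=1))
            if scale == 0:
                z = np.where(np.isnan(grp[col]), np.nan, 0.0)
            else:
                z = (grp[col].to_numpy(dtype=float) - center) / scale
            out.loc[grp.index, f"z_{col}"] = z
            ref_rows.append(
                dict(
                    barcode=barcode,
                    condition=condition,
                    parameter=col,
                    center=center,
                    scale=scale,
                )
            )
    return ZScoreTable(table=out, reference=pd.DataFrame(ref_rows))


def average_replicate_zscores(z: ZScoreTable) -> pd.DataFrame:
    """Mean of per-plate z-scores across replicate plates, per gene/role and
    condition (controls average over their wells)."""
    zcols = [f"z_{c}" for c in WELL_FEATURE_COLUMNS]
    df = z.table.copy()
    df["_key"] = np.where(
        df["gene"].astype(str) != "", df["gene"], "::" + df["role"].astype(str)
    )
    agg = {c: "mean" for c in zcols}
    agg["QC1_NoOfAnalysedCells"] = "mean"
    agg["role"] = "first"
    agg["gene"] = "first"
    return (
        df.groupby(["_key", "condition"], as_index=False)
        .agg(agg)
        .drop(columns=[])
        .rename(columns={"_key": "key"})
    )


def viability_gate(
    z: pd.DataFrame, z_viab: float = 2.0, min_cells: int = 50
) -> pd.Series:
    """True where a well/gene is excluded for cytotoxicity: strongly
    negative cell-count z-score or too few analyzed cells."""
    excluded = (z["z_QC1_NoOfAnalysedCells"] <= -z_viab) | (
        z["QC1_NoOfAnalysedCells"] < min_cells
    )
    return excluded.fillna(True)


def check_transfection_controls(z: pd.DataFrame, gate: pd.Series) -> bool:
    """Assay sanity check: every cytotoxic transfection-control (PLK1) entry
    must be caught by the viability gate."""
    is_plk1 = z["role"] == ROLE_TRANSFECTION_CTRL
    return bool(gate[is_plk1].all()) if is_plk1.any() else True


def _classify(zrow: dict[str, float], z_hit: float) -> tuple[bool, str]:
    def zval(p: str) -> float:
        v = zrow.get(f"z_{p}", np.nan)
        return float(v) if v is not None and not np.isnan(v) else 0.0

    z5 = zval("N5_PercentOfCellsWithSpots")
    z9 = zval("N9_NoOfSpotsPerCell")
    z1 = zval("N1_NucNotch")
    z3 = zval("N3_MembNotch")
    z4 = zval("N4_CellNotch")
    if z5 >= z_hit or z9 >= z_hit:
        if z3 <= -z_hit:
            return True, "altered_PM_and_intracellular"
        return True, "increased_intracellular"
    if z1 >= z_hit:
        return True, "increased_nuclear"
    if z4 <= -z_hit:
        # general loss of NOTCH1 signal: reported but not a localization hit
        return False, "decreased_total"
    return False, "none"


def call_hits(
    z: pd.DataFrame, gate: pd.Series, z_hit: float = 2.0
) -> list[HitCall]:
    """Call localization hits on (replicate-averaged) z-scores.

    A gene is a hit when a localization parameter crosses ``z_hit`` in a
    non-gated well and the excursion pattern maps to a phenotypic class:
    intracellular spot accumulation (N5/N9 up), the same with loss of
    surface signal (N3 down), or nuclear accumulation (N1 up). Wells whose
    only excursion is an overall signal loss (N4 down) are reported as
    ``decreased_total`` but excluded from the hit list.
    """
    calls: list[HitCall] = []
    zcols = [f"z_{c}" for c in WELL_FEATURE_COLUMNS]
    for idx, row in z.iterrows():
        gene = str(row.get("gene", "") or "")
        if not gene:
            continue
        zrow = {c: row.get(c, np.nan) for c in zcols}
        if bool(gate.loc[idx]):
            calls.append(
                HitCall(
                    gene=gene,
                    condition=str(row["condition"]),
                    hit=False,
                    phenotypic_class="none",
                    driving={},
                    viability_excluded=True,
                )
            )
            continue
        hit, cls = _classify(zrow, z_hit)
        driving = {
            p: float(zrow[f"z_{p}"])
            for p in LOCALIZATION_PARAMS
            if not np.isnan(zrow.get(f"z_{p}", np.nan))
            and abs(zrow[f"z_{p}"]) >= z_hit
        }
        calls.append(
            HitCall(
                gene=gene,
                condition=str(row["condition"]),
                hit=hit,
                phenotypic_class=cls,
                driving=driving,
            )
        )
    return calls


def combine_conditions(
    hits_noegta: list[HitCall], hits_egta: list[HitCall]
) -> ScreenTally:
    """Partition hit genes into only-unstimulated / only-stimulated / both
    and tally phenotypic classes; the union count is the primary hit total."""
    set_a = {h.gene for h in hits_noegta if h.hit}
    set_b = {h.gene for h in hits_egta if h.hit}
    genes_all = {h.gene for h in hits_noegta} | {h.gene for h in hits_egta}
    both = set_a & set_b
    tally = ScreenTally(
        n_screened=len(genes_all),
        n_primary_hits=len(set_a | set_b),
        n_only_NoEGTA=len(set_a - set_b),
        n_only_EGTA=len(set_b - set_a),
        n_both=len(both),
    )
    classes: dict[str, int] = {}
    for h in list(hits_noegta) + list(hits_egta):
        if h.hit:
            classes[h.phenotypic_class] = classes.get(h.phenotypic_class, 0) + 1
    tally.class_counts = classes
    return tally


def reconcile_screens(
    primary: list[HitCall], secondary: list[HitCall]
) -> list[str]:
    """Genes confirmed by the validation screen: hit in both screens with
    the same phenotypic class under the same condition."""
    prim = {
        (h.gene, h.condition): h.phenotypic_class for h in primary if h.hit
    }
    confirmed = sorted(
        {
            h.gene
            for h in secondary
            if h.hit and prim.get((h.gene, h.condition)) == h.phenotypic_class
        }
    )
    return confirmed


def percentage(n: int, total: int, ndigits: int = 1) -> float:
    """Share of a tally as a percentage, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(100.0 * n / total, ndigits)


def p_to_stars(p: float) -> str:
    """Significance tiers: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001,
    ns otherwise."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_stars(a, b) -> tuple[float, float, str]:
    """Welch two-sample two-tailed t test with the usual star labels."""
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "ns"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(t), float(p)
    if np.isnan(p):
        p = 1.0
    return t, p, p_to_stars(p)
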