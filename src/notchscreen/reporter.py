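"""RBPJk-luciferase reporter screen analysis.

Luminescence (Notch transcriptional output) is normalized by the resazurin
viability readout so that slow-growing knockdowns are not mistaken for
signaling suppressors, expressed as a fold change against the non-targeting
wells of the same plate and condition, and classified with the inclusive
30%-modulation rule; signaling calls are then merged with the confirmed
localization hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import ROLE_NT
from .screenstats import percentage

logger = logging.getLogger(__name__)

__all__ = [
    "SignalingCall",
    "normalize_reporter",
    "classify_signaling",
    "classify_signaling_table",
    "assay_window",
    "merge_localization_signaling",
]


@dataclass(frozen=True)
class SignalingCall:
    gene: str
    condition: str
    direction: str  # suppressor | enhancer | none
    fold_change: float
    assay_window_ok: bool = True


def normalize_reporter(
    table: pd.DataFrame, *, viability_floor: float = 0.0
) -> pd.DataFrame:
    """Viability-normalize reporter wells and compute fold change vs NT.

    ``normalized`` = luminescence / viability; ``fold_change`` divides by
    the median normalized value of the non-targeting wells on the same
    plate and condition (so the NT median fold change is exactly 1). Wells
    with non-positive or sub-floor viability are dropped with a warning.
    """
    df = table.copy()
    bad = df["viability"] <= max(viability_floor, 0.0)
    if bad.any():
        logger.warning("excluding %d wells with non-positive viability", int(bad.sum()))
        df = df[~bad].copy()
    df["normalized"] = df["luminescence"] / df["viability"]
    df["fold_change"] = np.nan
    for (barcode, condition), grp in df.groupby(["barcode", "condition"]):
        nt = grp[grp["role"] == ROLE_NT]
        if len(nt) < 4:
            raise ValueError(
                f"plate {barcode}/{condition}: need >= 4 NT wells, got {len(nt)}"
            )
        ref = float(nt["normalized"].median())
        df.loc[grp.index, "fold_change"] = grp["normalized"] / ref
    return df


def classify_signaling(
    gene: str,
    condition: str,
    fold_change: float,
    threshold: float = 0.30,
    assay_window_ok: bool = True,
) -> SignalingCall:
    """Classify one fold change with the inclusive modulation rule:
    fold <= 1 - threshold is a suppressor, fold >= 1 + threshold an
    enhancer, anything else none."""
    if fold_change <= 0 or np.isnan(fold_change):
        raise ValueError("fold_change must be > 0")
    if fold_change <= 1.0 - threshold:
        direction = "suppressor"
    elif fold_change >= 1.0 + threshold:
        direction = "enhancer"
    else:
        direction = "none"
    return SignalingCall(
        gene=gene,
        condition=condition,
        direction=direction,
        fold_change=float(fold_change),
        assay_window_ok=assay_window_ok,
    )


def classify_signaling_table(
    normalized: pd.DataFrame,
    threshold: float = 0.30,
    *,
    sample_role: str = "sample",
) -> list[SignalingCall]:
    """Per-gene signaling calls from a normalized reporter table; replicate
    wells of a gene x condition are combined by their median fold change."""
    df = normalized[normalized["role"] == sample_role]
    calls = []
    for (gene, condition), grp in df.groupby(["gene", "condition"]):
        fold = float(grp["fold_change"].median())
        calls.append(classify_signaling(str(gene), str(condition), fold, threshold))
    return calls


def assay_window(
    normalized: pd.DataFrame, stim_factor_min: float = 2.0
) -> tuple[float, bool]:
    """EGTA induction window of a plate pair: ratio of the median normalized
    NT signal with EGTA to without. The assay is valid when the window
    reaches ``stim_factor_min`` (inclusive)."""
    nt = normalized[normalized["role"] == ROLE_NT]
    med = {}
    for condition in ("NoEGTA", "EGTA"):
        vals = nt.loc[nt["condition"] == condition, "normalized"]
        if len(vals) == 0:
            raise ValueError(f"no NT wells for condition {condition}")
        med[condition] = float(vals.median())
    window = med["EGTA"] / med["NoEGTA"]
    return window, window >= stim_factor_min


def merge_localization_signaling(
    confirmed_genes: list[str],
    signaling_calls: list[SignalingCall],
    localization_classes: dict[str, str] | None = None,
) -> dict:
    """Join confirmed localization hits with their signaling behaviour.

    Returns per-gene records plus the screen's summary tallies: modulator,
    suppressor and enhancer counts, the per-condition breakdown
    (unstimulated only / stimulated only / both) and the percentage of
    confirmed localization hits that modulate signaling (1 decimal).
    """
    confirmed = list(dict.fromkeys(confirmed_genes))
    by_gene: dict[str, list[SignalingCall]] = {}
    for c in signaling_calls:
        if c.gene in set(confirmed):
            by_gene.setdefault(c.gene, []).append(c)

    records = []
    modulators, suppressors, enhancers = set(), set(), set()
    mod_conditions: dict[str, set[str]] = {}
    for gene in confirmed:
        calls = by_gene.get(gene, [])
        for c in calls:
            if c.direction != "none":
                modulators.add(gene)
                mod_conditions.setdefault(gene, set()).add(c.condition)
                (suppressors if c.direction == "suppressor" else enhancers).add(gene)
        records.append(
            dict(
                gene=gene,
                localization_class=(localization_classes or {}).get(gene, ""),
                directions={c.condition: c.direction for c in calls},
                fold_changes={c.condition: c.fold_change for c in calls},
            )
        )
    unstim_only = sum(
        1 for g in modulators if mod_conditions[g] == {"NoEGTA"}
    )
    stim_only = sum(1 for g in modulators if mod_conditions[g] == {"EGTA"})
    both = sum(
        1 for g in modulators if mod_conditions[g] == {"NoEGTA", "EGTA"}
    )
    n_mod = len(modulators)
    pct = percentage(n_mod, len(confirmed)) if confirmed else 0.0
    return {
        "records": records,
        "n_confirmed": len(confirmed),
        "n_signaling_modulators": n_mod,
        "n_suppressors": len(suppressors),
        "n_enhancers": len(enhancers),
        "n_unstim_only": unstim_only,
        "n_stim_only": stim_only,
        "n_both_conditions": both,
        "pct_modulating": pct,
    }
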