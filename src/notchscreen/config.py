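"""Run configuration: every tunable threshold of the pipeline in one
serializable object, hashed into output metadata so that artifacts from
different configurations cannot be mixed in a report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # simulation
    seed: int = 0
    n_sample_wells: int = 20
    fields_per_well: int = 8
    mean_cells_per_field: float = 25.0
    oof_fraction: float = 0.05
    field_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.65
    # segmentation
    ring_width_px: int = 3
    min_cell_area: int = 200
    max_cell_area: int = 20000
    min_solidity: float = 0.8
    sat_frac: float = 0.005
    # focus QC
    fence_k: float = 1.5
    focus_min_frac: float = 0.5
    # spots
    snr_threshold: float = 5.0
    spot_sigma_px: float = 1.5
    spot_min: int = 2
    # hit calling
    z_hit: float = 2.0
    z_viab: float = 2.0
    min_cells: int = 50
    # reporter
    modulation_threshold: float = 0.30
    stim_factor_min: float = 2.0
    # colocalization
    coloc_intensity_threshold: float = 4.0
    coloc_max_distance_px: float = 2.0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.oof_fraction <= 1, "oof_fraction in [0,1]"),
            (self.ring_width_px >= 0, "ring_width_px >= 0"),
            (0 < self.min_cell_area < self.max_cell_area, "cell area bounds"),
            (0 <= self.sat_frac <= 1, "sat_frac in [0,1]"),
            (self.fence_k > 0, "fence_k > 0"),
            (0 < self.focus_min_frac < 1, "focus_min_frac in (0,1)"),
            (self.snr_threshold > 0, "snr_threshold > 0"),
            (self.spot_sigma_px > 0, "spot_sigma_px > 0"),
            (self.z_hit > 0, "z_hit > 0"),
            (0 < self.modulation_threshold < 1, "modulation_threshold in (0,1)"),
            (self.coloc_max_distance_px > 0, "coloc_max_distance_px > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_shape"] = list(self.field_shape)
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "field_shape" in data:
            data["field_shape"] = tuple(data["field_shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
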