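"""File-format contracts: multi-page TIFF fields, label-image TIFFs, truth
JSON sidecars, and CSV tables with an embedded config-hash header line."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ORDER = ["DAPI", "phalloidin", "NOTCH1"]


def field_stem(barcode: str, well: str, fld: int) -> str:
    return f"{barcode}_{well}_{fld:02d}"


def write_field_tiff(path: Path, channels: dict[str, np.ndarray]) -> None:
    """Write a field as a 3-page TIFF in DAPI/phalloidin/NOTCH1 order."""
    stack = np.stack([np.asarray(channels[c]) for c in CHANNEL_ORDER])
    tifffile.imwrite(path, stack.astype(np.uint16), photometric="minisblack")


def read_field_tiff(path: Path) -> dict[str, np.ndarray]:
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # corrupt or unreadable file
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if stack.ndim != 3 or stack.shape[0] != len(CHANNEL_ORDER):
        raise IOError(f"{path}: expected {len(CHANNEL_ORDER)}-page TIFF")
    return {c: stack[i] for i, c in enumerate(CHANNEL_ORDER)}


def write_labels_tiff(path: Path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, labels.astype(np.int32))


def write_truth_json(path: Path, truth) -> None:
    payload = {
        "blur_sigma": truth.blur_sigma,
        "is_out_of_focus": truth.is_out_of_focus,
        "spots": [[x, y, cid] for x, y, cid in truth.spots],
        "compartment_sums": {
            str(k): v for k, v in truth.compartment_sums.items()
        },
    }
    path.write_text(json.dumps(payload))


def write_table(path: Path, df: pd.DataFrame, config_hash: str) -> None:
    """CSV with a leading ``# config_hash=...`` comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path) -> tuple[pd.DataFrame, str | None]:
    """Read a pipeline CSV, returning (table, embedded config hash)."""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# config_hash="):
            chash = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            chash = None
            fh.seek(0)
            df = pd.read_csv(fh)
    return df, chash


def write_json(path: Path, payload: dict, config_hash: str) -> None:
    payload = dict(payload)
    payload["config_hash"] = config_hash
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())
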