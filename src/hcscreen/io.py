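"""File formats: multi-page TIFF fields with JSON sidecars, layout and
well-summary CSVs, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CHANNEL_NAMES, FieldImage
from .synthgen import PlateLayout


def write_field(field: FieldImage, path: str | Path) -> Path:
    """Write a field as multi-page TIFF (one page per channel) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, field.channels.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "channel_names": list(field.channel_names),
        "pixel_size_um": field.pixel_size_um,
        "well": field.well,
        "field_index": field.field_index,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_field(path: str | Path) -> FieldImage:
    path = Path(path)
    channels = np.asarray(tifffile.imread(path), dtype=float)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return FieldImage(
        channels=channels,
        channel_names=tuple(meta.get("channel_names", CHANNEL_NAMES)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.65)),
        well=meta.get("well", ""),
        field_index=int(meta.get("field_index", 0)),
    )


def write_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    df = layout.wells.copy()
    df.insert(0, "format", layout.format)
    df.to_csv(path, index=False)
    return path


def read_layout(path: str | Path) -> PlateLayout:
    df = pd.read_csv(path)
    fmt = int(df["format"].iloc[0])
    wells = df.drop(columns=["format"])
    wells["compound_id"] = wells["compound_id"].where(wells["compound_id"].notna(), None)
    return PlateLayout(format=fmt, wells=wells)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
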