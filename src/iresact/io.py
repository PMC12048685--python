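"""File I/O: multi-page TIFF image stacks with channel metadata, truth sidecars, tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .smfish import ImageStack

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "write_table",
]


def write_image_stack(stack: ImageStack, path) -> None:
    """Write channels as a multi-page float32 TIFF; roles go in the page description."""
    roles = sorted(stack.channels)
    data = np.stack([stack.channels[r] for r in roles]).astype(np.float32)
    meta = {
        "channels": roles,
        "region_label": stack.region_label,
        "embryo_id": stack.embryo_id,
        "pixel_size_um": stack.pixel_size,
    }
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_image_stack(path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    channels = {role: data[i] for i, role in enumerate(meta["channels"])}
    return ImageStack(
        channels=channels,
        pixel_size=meta.get("pixel_size_um"),
        region_label=meta.get("region_label", ""),
        embryo_id=meta.get("embryo_id", ""),
    )


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_truth_sidecar(truth, path) -> None:
    """Serialize a truth dataclass as a YAML sidecar next to the generated data."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth), fh, sort_keys=True)


def read_truth_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV or CSV by extension (default TSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
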