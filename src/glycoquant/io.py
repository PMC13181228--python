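"""TIFF / CSV / YAML / JSON interchange.

Images travel as multipage TIFF with the channel order recorded in the
page description (JSON); label masks as 16-bit TIFF; tables as CSV;
configuration as YAML; scalar reports and provenance as JSON.  Integer
image inputs are promoted to floating intensities without rescaling.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .segmentation import ChannelStack


def write_stack(path: str | Path, stack: ChannelStack, channel_order: Sequence[str] | None = None) -> None:
    """Write one page per channel; the channel order goes into the TIFF
    description so a bare ``read_stack(path)`` can restore the names."""
    names = list(channel_order) if channel_order is not None else sorted(stack.channels)
    missing = [n for n in names if n not in stack]
    if missing:
        raise KeyError(f"channels {missing} not in stack")
    data = np.stack([stack[n] for n in names])
    tifffile.imwrite(path, data, photometric="minisblack", description=json.dumps({"channels": names}))


def read_stack(path: str | Path, channel_map: Mapping[str, int] | Sequence[str] | None = None) -> ChannelStack:
    """Read a multipage TIFF into named channels.

    ``channel_map`` is either a name → page-index mapping, a list of names
    in page order, or None to use the names stored in the TIFF description.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray().astype(float) for p in tif.pages]
        description = tif.pages[0].description or ""
    if pages and pages[0].ndim == 3:  # single page holding a (C, H, W) stack
        pages = [plane.astype(float) for plane in pages[0]]
    if channel_map is None:
        try:
            names = json.loads(description)["channels"]
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValueError(f"{path}: no channel names in TIFF metadata; pass channel_map") from None
        channel_map = names
    if isinstance(channel_map, Mapping):
        items = list(channel_map.items())
    else:
        items = [(name, i) for i, name in enumerate(channel_map)]
    channels = {}
    for name, idx in items:
        if not 0 <= idx < len(pages):
            raise KeyError(f"channel {name!r} maps to page {idx} but file has pages 0..{len(pages) - 1}")
        channels[name] = pages[idx]
    return ChannelStack(channels)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
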