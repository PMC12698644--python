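"""Disk formats: multi-page event TIFFs and channel-map metadata.

Each event is one multi-page TIFF, one float32 page per channel in the
profile's channel order; the channel map rides along as a JSON image
description so files are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import tifffile

from .simulate import EventImage

__all__ = ["write_event_tiff", "read_event_tiff"]


def write_event_tiff(path: str | Path, image: EventImage) -> None:
    meta = {
        "channel_map": image.channel_map,
        "pixel_size_um": image.pixel_size_um,
        "event_id": image.event_id,
    }
    tifffile.imwrite(
        str(path), image.pixels.astype(np.float32),
        description=json.dumps(meta), photometric="minisblack",
    )


def read_event_tiff(
    path: str | Path,
    channel_map: Optional[Dict[str, int]] = None,
    pixel_size_um: Optional[float] = None,
    event_id: Optional[str] = None,
) -> EventImage:
    """Read one event back; metadata from the file unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if pixels.ndim == 2:
        pixels = pixels[None, ...]
    cmap = channel_map or meta.get("channel_map")
    if cmap is None:
        raise ValueError(f"{path}: no channel map in file and none supplied")
    return EventImage(
        pixels=pixels.astype(np.float32),
        channel_map={str(k): int(v) for k, v in cmap.items()},
        pixel_size_um=float(pixel_size_um or meta.get("pixel_size_um", 0.5)),
        event_id=str(event_id or meta.get("event_id", path.stem)),
    )
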