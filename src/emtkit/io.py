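"""File I/O: multi-channel TIFF images, mask/label rasters, tidy TSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .types import LabelMap, MultiplexImage


def write_multiplex_tiff(image: MultiplexImage, path) -> None:
    """Write channels as TIFF pages; channel names go in the image
    description metadata."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    meta = {"channel_names": names}
    if image.pixel_size is not None:
        meta["pixel_size_um"] = image.pixel_size
    tifffile.imwrite(str(path), stack, description=json.dumps(meta))


def read_multiplex_tiff(path) -> MultiplexImage:
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    names = meta.get(
        "channel_names", [f"channel_{i}" for i in range(stack.shape[0])]
    )
    channels = {name: stack[i] for i, name in enumerate(names)}
    return MultiplexImage(channels=channels,
                          pixel_size=meta.get("pixel_size_um"))


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_labels_tiff(labels: LabelMap, path) -> None:
    tifffile.imwrite(str(path), labels.labels.astype(np.uint16))


def write_sidecar(path, **params) -> None:
    """JSON sidecar recording thresholds/parameters next to an output."""
    Path(path).write_text(json.dumps(params, indent=2, default=float) + "\n")
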