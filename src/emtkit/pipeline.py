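"""End-to-end conveniences tying segmentation, quantification and
statistics together on image collections."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort_stats import StatResult, paired_correlation
from .quantification import quantify_compartments
from .segmentation import segment_compartments
from .types import MultiplexImage


def quantify_regions(
    regions: Sequence[MultiplexImage],
    markers: Sequence[str],
    panck_method="otsu",
    krt5_method="otsu",
) -> pd.DataFrame:
    """Segment and quantify a list of region images into one tidy table."""
    tables = []
    for i, image in enumerate(regions):
        masks = segment_compartments(image, panck_method, krt5_method)
        tables.append(
            quantify_compartments(image, masks, markers, region_id=i)
        )
    return pd.concat(tables, ignore_index=True)


def region_correlation(
    regions: Sequence[MultiplexImage],
    compartment: str,
    marker_x: str,
    marker_y: str,
    **kwargs,
) -> Tuple[StatResult, pd.DataFrame]:
    """Recover the inter-marker correlation of a region set through the
    full image pipeline (threshold, compartment masks, alpha, Pearson r)."""
    quant = quantify_regions(regions, (marker_x, marker_y), **kwargs)
    sub = quant[quant["compartment"] == compartment]
    wide = sub.pivot_table(index="region_id", columns="marker", values="alpha")
    wide = wide.dropna(subset=[marker_x, marker_y])
    result = paired_correlation(
        wide[marker_x].to_numpy(), wide[marker_y].to_numpy(), "pearson"
    )
    return result, wide
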