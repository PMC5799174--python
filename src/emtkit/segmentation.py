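"""Compartment and object segmentation for multiplex-IHC images.

The tissue workflow thresholds the pan-cytokeratin (panCK) channel to find
epithelium, the cytokeratin-5 (KRT5) channel to find basal/benign epithelium,
and defines cancer epithelium as panCK+/KRT5- and stroma as the inversion of
the epithelial mask.  Object detection mirrors a binary distance-transform
watershed followed by a particle-size filter, and the screen workflow labels
whole cells by expanding detected nuclei.

Thresholds default to Otsu's method with a fixed-value override; the
threshold actually used is returned so it can be recorded alongside output
masks.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import expand_labels, watershed

from .types import CompartmentMasks, DegenerateInputError, LabelMap, MultiplexImage

Method = Union[str, Tuple[str, float]]

#: minimum separation (px) between watershed seed maxima
SEED_MIN_DISTANCE = 5


def _resolve_threshold(raster: np.ndarray, method: Method) -> float:
    if method == "otsu":
        if raster.min() == raster.max():
            raise DegenerateInputError(
                "Otsu threshold undefined on a constant image"
            )
        # skimage's Otsu cut marks foreground as value > cut; masks here use
        # value >= threshold, so move the threshold to the midpoint between
        # the cut and the next observed value above it.
        cut = float(threshold_otsu(raster))
        above = raster[raster > cut]
        if above.size == 0:
            return cut
        return (cut + float(above.min())) / 2.0
    if isinstance(method, tuple) and len(method) == 2 and method[0] == "fixed":
        return float(method[1])
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_channel(
    image: MultiplexImage, channel: str, method: Method = "otsu"
) -> Tuple[np.ndarray, float]:
    """Binarise one channel; mask is true where intensity >= threshold.

    Returns ``(mask, threshold_used)``.
    """
    raster = image.channel(channel)
    thr = _resolve_threshold(raster, method)
    return raster >= thr, thr


def segment_compartments(
    image: MultiplexImage,
    panck_method: Method = "otsu",
    krt5_method: Method = "otsu",
) -> CompartmentMasks:
    """Split a core into epithelium / KRT5+ / cancer epithelium / stroma.

    Epithelium is the panCK mask; KRT5-positive (benign/basal) epithelium is
    the intersection with the KRT5 mask; cancer epithelium is panCK+/KRT5-;
    stroma is everything outside the epithelium.  A KRT5 channel that carries
    no signal yields an empty ``krt5_pos`` and ``cancer_epi == epithelium``
    (a fixed threshold of 0 would instead mark everything KRT5+, so an
    all-zero KRT5 channel is special-cased to empty).
    """
    epithelium, _ = threshold_channel(image, "panCK", panck_method)
    krt5_raster = image.channel("KRT5")
    if krt5_raster.max(initial=0) == 0:
        krt5_mask = np.zeros_like(epithelium, dtype=bool)
    else:
        krt5_mask, _ = threshold_channel(image, "KRT5", krt5_method)
    krt5_pos = epithelium & krt5_mask
    return CompartmentMasks(
        epithelium=epithelium,
        krt5_pos=krt5_pos,
        cancer_epi=epithelium & ~krt5_mask,
        stroma=~epithelium,
    )


def _watershed_labels(mask: np.ndarray) -> np.ndarray:
    """Distance-transform watershed of a boolean mask."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=SEED_MIN_DISTANCE, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # mask thinner than any local maximum: keep blobs
        markers, _ = ndi.label(mask)
    return watershed(-distance, markers, mask=mask)


def _filter_and_relabel(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Drop objects with area <= min_area and relabel contiguously (stable
    order by original label id)."""
    out = np.zeros(labels.shape, dtype=np.int32)
    next_id = 1
    for lab in np.unique(labels[labels > 0]):
        region = labels == lab
        if int(region.sum()) > min_area:
            out[region] = next_id
            next_id += 1
    return out


def split_objects(mask: np.ndarray, min_area: int = 100) -> LabelMap:
    """Watershed-split a mask into objects, keeping areas strictly > min_area.

    Emulates binary watershed + particle analysis with a 100 px particle
    filter: touching convex blobs are cut at the distance-transform saddle,
    and only objects larger than ``min_area`` pixels are retained as true
    objects.  An empty mask yields an empty label map.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _watershed_labels(mask)
    return LabelMap(_filter_and_relabel(labels, min_area), min_area=min_area)


def segment_cells(
    image: MultiplexImage,
    expansion_radius: float = 5,
    nuclei_method: Method = "otsu",
    min_nucleus_area: int = 4,
) -> LabelMap:
    """Label whole cells by nucleus detection plus fixed-radius expansion.

    Nuclei are detected on the Hoechst channel (threshold + distance
    watershed), then each nucleus is grown by ``expansion_radius`` pixels;
    contested pixels go to the nearest nucleus, so cell regions partition the
    expanded area with no double assignment.
    """
    raster = image.channel("Hoechst")
    if raster.max(initial=0) == 0:
        raise DegenerateInputError("no nuclei found (empty Hoechst channel)")
    nuclei_mask, _ = threshold_channel(image, "Hoechst", nuclei_method)
    nuclei = _filter_and_relabel(_watershed_labels(nuclei_mask), min_nucleus_area)
    if nuclei.max() == 0:
        raise DegenerateInputError("no nuclei found after size filtering")
    return LabelMap(expand_labels(nuclei, distance=expansion_radius))
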