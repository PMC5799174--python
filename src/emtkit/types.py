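"""Core containers shared across the pipeline.

Images are stacks of equally shaped 8-bit channel rasters keyed by stain
name (``panCK``, ``KRT5``, ``Hoechst`` plus marker channels such as ``CAV1``,
``ECADH`` or ``ITGB1``).  Compartment masks are boolean rasters tied together
by the mask algebra the tissue analysis relies on: epithelium is the panCK+
area, cancer epithelium is panCK+/KRT5-, and stroma is the complement of the
epithelium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is degenerate for the requested operation
    (constant image for Otsu, empty mask for an intensity average, ...)."""


@dataclass
class MultiplexImage:
    """Named stack of equal-shape 8-bit intensity rasters, one per channel."""

    channels: Mapping[str, np.ndarray]
    pixel_size: Optional[float] = None  # um / px, metadata only

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {
            name: np.asarray(raster) for name, raster in self.channels.items()
        }

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not in image (has {sorted(self.channels)})"
            )
        return self.channels[name]


@dataclass
class CompartmentMasks:
    """Boolean compartment rasters with the tissue mask algebra enforced.

    Invariants (checked on construction):

    * ``krt5_pos`` is contained in ``epithelium``
    * ``cancer_epi == epithelium & ~krt5_pos``
    * ``stroma == ~epithelium``
    * ``cancer_epi`` and ``krt5_pos`` are disjoint
    """

    epithelium: np.ndarray
    krt5_pos: np.ndarray
    cancer_epi: np.ndarray
    stroma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("epithelium", "krt5_pos", "cancer_epi", "stroma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (
            self.epithelium.shape
            == self.krt5_pos.shape
            == self.cancer_epi.shape
            == self.stroma.shape
        ):
            raise ValueError("mask shapes differ")
        if np.any(self.krt5_pos & ~self.epithelium):
            raise ValueError("krt5_pos must be a subset of epithelium")
        if not np.array_equal(self.cancer_epi, self.epithelium & ~self.krt5_pos):
            raise ValueError("cancer_epi must equal epithelium & ~krt5_pos")
        if not np.array_equal(self.stroma, ~self.epithelium):
            raise ValueError("stroma must be the complement of epithelium")

    def by_name(self, compartment: str) -> np.ndarray:
        return getattr(self, compartment)


@dataclass
class LabelMap:
    """Integer object labels (0 = background) with per-object pixel areas."""

    labels: np.ndarray
    min_area: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def areas(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))
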