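"""Region and object intensity quantification and score categorisation.

The central read-out is the average protein expression intensity

    alpha = (total channel intensity) / (total area in pixels)

computed over a compartment mask or region.  Visual-scale scores are binned
into the four categories used for the TMA cohort:

    Negative  x = 0
    Weak      0 < x <= 1
    Moderate  1 < x < 2
    Strong    x >= 2

and patient-level scores are the unweighted mean over that patient's cancer
cores, with patients contributing fewer than two cancer cores flagged as
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import DegenerateInputError, LabelMap, MultiplexImage

CATEGORIES = ("Negative", "Weak", "Moderate", "Strong")


def alpha_intensity(
    image: MultiplexImage, mask: np.ndarray, channel: str
) -> Tuple[float, int]:
    """Mean intensity over a mask: total channel intensity / pixel area.

    All masked pixels count, including zeros.  Returns ``(alpha, area_px)``.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise DegenerateInputError("empty mask: alpha undefined")
    raster = image.channel(channel)
    total = float(np.asarray(raster, dtype=np.float64)[mask].sum())
    return total / area, area


def object_stats(
    image: MultiplexImage, labels: LabelMap, channel: str
) -> pd.DataFrame:
    """Per-object area, mean and median intensity (one row per object)."""
    raster = np.asarray(image.channel(channel), dtype=np.float64)
    lab = labels.labels
    rows = []
    for obj_id in np.unique(lab[lab > 0]):
        values = raster[lab == obj_id]
        rows.append(
            {
                "object_id": int(obj_id),
                "area": int(values.size),
                "mean": float(values.mean()),
                "median": float(np.median(values)),
            }
        )
    return pd.DataFrame(rows, columns=["object_id", "area", "mean", "median"])


def categorize_score(x: float) -> str:
    """Bin a non-negative score into Negative/Weak/Moderate/Strong."""
    if x < 0:
        raise ValueError(f"score must be non-negative, got {x}")
    if x == 0:
        return "Negative"
    if x <= 1:
        return "Weak"
    if x < 2:
        return "Moderate"
    return "Strong"


def category_counts(scores: Iterable[float]) -> pd.Series:
    cats = pd.Categorical(
        [categorize_score(x) for x in scores], categories=list(CATEGORIES)
    )
    return pd.Series(cats).value_counts().reindex(list(CATEGORIES))


def category_percentages(counts: Sequence[int]) -> np.ndarray:
    """Category shares in percent over the column's own total."""
    counts = np.asarray(counts, dtype=float)
    return 100.0 * counts / counts.sum()


@dataclass
class PatientScore:
    patient_id: object
    marker: str
    score: Optional[float]
    category: Optional[str]
    n_cancer_cores: int
    excluded: bool


def aggregate_patient(records: pd.DataFrame) -> PatientScore:
    """Patient-level score: unweighted mean over cancer cores.

    ``records`` holds one patient's core scores with columns
    ``patient_id, core_type, marker, score``.  Patients with fewer than two
    cancer cores are flagged excluded (score still reported when one core
    exists, category withheld).
    """
    if records.empty:
        raise ValueError("no records for patient")
    if records["patient_id"].nunique() != 1 or records["marker"].nunique() != 1:
        raise ValueError("records must share one patient_id and one marker")
    cancer = records.loc[records["core_type"] == "cancer", "score"]
    n = int(cancer.shape[0])
    excluded = n < 2
    score = float(cancer.mean()) if n else None
    return PatientScore(
        patient_id=records["patient_id"].iloc[0],
        marker=records["marker"].iloc[0],
        score=score,
        category=None if excluded else categorize_score(score),
        n_cancer_cores=n,
        excluded=excluded,
    )


def quantify_compartments(
    image: MultiplexImage,
    masks,
    markers: Sequence[str],
    compartments: Sequence[str] = ("krt5_pos", "cancer_epi", "stroma"),
    **ids,
) -> pd.DataFrame:
    """Tidy table of alpha per (compartment, marker); empty compartments are
    skipped (no-compartment regions are excluded upstream)."""
    rows = []
    for comp in compartments:
        mask = masks.by_name(comp)
        if not mask.any():
            continue
        for marker in markers:
            alpha, area = alpha_intensity(image, mask, marker)
            rows.append(
                dict(ids, compartment=comp, marker=marker, alpha=alpha, area=area)
            )
    return pd.DataFrame(rows)
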