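"""Synthetic TMA cohorts: per-patient scores, cores and clinical labels.

Emulates the TMA design of the emulated study population: each patient
contributes one benign and several cancer cores; visual-scale marker scores
(0-3 for CAV1) live at the patient level with core-level noise, and
clinical labels (Gleason-score group, pathological stage group) are sampled
from a proportional-odds logistic link on the patient's latent CAV1 level
whose slope defaults to zero — the cohort analysis found no association, so
the null must be generable and the association strength is a dial for power
studies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ..quantification import categorize_score
from ._random import correlated_pair
from .tissue import MarkerModel, TissueSimSpec, generate_tissue_core

GLEASON_GROUPS = ("<=6", "7", ">=8")
STAGE_GROUPS = ("<=pT2", "pT3<=")


@dataclass
class ClinicalModel:
    """Clinical-label model: baseline group frequencies (from the cohort
    marginals) and the log-odds slope of latent CAV1 on each axis."""

    gleason_base: Tuple[float, float, float] = (0.24, 0.59, 0.17)
    stage_base: Tuple[float, float] = (0.58, 0.42)
    gleason_slope: float = 0.0
    stage_slope: float = 0.0
    exclusion_rate: float = 0.0  # neo-adjuvant / missing-data exclusions


@dataclass
class CohortSimSpec:
    """Score-level cohort model (visual 0-3 scale unless noted)."""

    benign_mean: float = 0.35
    cancer_mean: float = 0.90
    latent_sd: float = 0.85
    core_sd: float = 0.25
    #: patient-level latent correlation between the two markers in cancer
    marker_rho: float = -0.6
    markers: Tuple[str, str] = ("CAV1", "ECADH")
    ecadh_benign_mean: float = 2.2
    ecadh_cancer_mean: float = 1.6
    #: a.u. of image intensity per visual-score unit, for rendered cores
    alpha_per_score: float = 60.0
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    empirical: bool = False
    seed: int = 0


def _ordinal_sample(
    rng: np.random.Generator,
    base: Tuple[float, ...],
    latent: np.ndarray,
    slope: float,
) -> np.ndarray:
    """Proportional-odds draw: shift the baseline cumulative logits by
    slope * standardised latent."""
    base = np.asarray(base, dtype=float)
    base = base / base.sum()
    if slope == 0.0:
        return rng.choice(len(base), size=latent.size, p=base)
    cum = np.cumsum(base)[:-1]
    logits = np.log(cum / (1.0 - cum))
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    out = np.empty(latent.size, dtype=int)
    for i, zi in enumerate(z):
        c = 1.0 / (1.0 + np.exp(-(logits - slope * zi)))
        p = np.diff(np.concatenate([[0.0], c, [1.0]]))
        out[i] = rng.choice(len(base), p=p / p.sum())
    return out


def generate_cohort(
    spec: CohortSimSpec,
    n_patients: int,
    cores_per_patient: int = 4,
    render: bool = False,
    tissue_spec: Optional[TissueSimSpec] = None,
) -> dict:
    """Generate a cohort truth table (and optionally rendered cores).

    Each patient gets one benign core and ``cores_per_patient - 1`` cancer
    cores.  Returns a dict with ``patients`` (patient-level truth: latent
    scores, Gleason group, stage group, exclusion flag), ``cores`` (per-core
    scores and alpha ground truth) and, when ``render`` is set, ``images``
    (list of (patient_id, core_id, MultiplexImage)).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if cores_per_patient < 2:
        raise ValueError("need >= 2 cores per patient (>=1 benign, >=1 cancer)")
    rng = np.random.default_rng(spec.seed)
    m0, m1 = spec.markers

    lat_cancer = correlated_pair(
        n_patients,
        (spec.cancer_mean, spec.ecadh_cancer_mean),
        (spec.latent_sd, spec.latent_sd),
        spec.marker_rho,
        rng,
        empirical=spec.empirical and n_patients >= 3,
    )
    lat_benign = np.column_stack(
        [
            spec.benign_mean + spec.latent_sd * rng.standard_normal(n_patients),
            spec.ecadh_benign_mean + spec.latent_sd * rng.standard_normal(n_patients),
        ]
    )
    lat_cancer = np.clip(lat_cancer, 0.0, None)
    lat_benign = np.clip(lat_benign, 0.0, None)

    clin = spec.clinical
    gleason = _ordinal_sample(rng, clin.gleason_base, lat_cancer[:, 0],
                              clin.gleason_slope)
    stage = _ordinal_sample(rng, clin.stage_base, lat_cancer[:, 0],
                            clin.stage_slope)
    excluded = rng.random(n_patients) < clin.exclusion_rate

    core_rows: List[dict] = []
    for p in range(n_patients):
        for k in range(cores_per_patient):
            core_type = "benign" if k == 0 else "cancer"
            lat = lat_benign[p] if core_type == "benign" else lat_cancer[p]
            for j, marker in enumerate((m0, m1)):
                score = lat[j]
                if spec.core_sd > 0:
                    score = score + spec.core_sd * rng.standard_normal()
                score = float(np.clip(score, 0.0, None))
                core_rows.append(
                    {
                        "patient_id": p,
                        "core_id": k,
                        "core_type": core_type,
                        "marker": marker,
                        "score": score,
                        "alpha_true": score * spec.alpha_per_score,
                    }
                )
    cores = pd.DataFrame(core_rows)

    cancer_scores = (
        cores[(cores["core_type"] == "cancer") & (cores["marker"] == m0)]
        .groupby("patient_id")["score"]
        .mean()
    )
    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n_patients),
            f"latent_{m0}_cancer": lat_cancer[:, 0],
            f"latent_{m1}_cancer": lat_cancer[:, 1],
            f"latent_{m0}_benign": lat_benign[:, 0],
            f"latent_{m1}_benign": lat_benign[:, 1],
            "gleason_group": [GLEASON_GROUPS[i] for i in gleason],
            "stage_group": [STAGE_GROUPS[i] for i in stage],
            "excluded": excluded,
            f"score_{m0}_cancer": cancer_scores.reindex(
                np.arange(n_patients)
            ).to_numpy(),
        }
    )
    patients[f"category_{m0}"] = [
        categorize_score(s) for s in patients[f"score_{m0}_cancer"]
    ]

    out = {"patients": patients, "cores": cores}
    if render:
        out["images"] = _render_cores(spec, cores, tissue_spec, rng)
    return out


def _render_cores(
    spec: CohortSimSpec,
    cores: pd.DataFrame,
    tissue_spec: Optional[TissueSimSpec],
    rng: np.random.Generator,
) -> list:
    base = tissue_spec or TissueSimSpec(image_size=128, n_glands=2,
                                        gland_radius=(16.0, 24.0))
    images = []
    for (p, k), sub in cores.groupby(["patient_id", "core_id"]):
        core_type = sub["core_type"].iloc[0]
        comp = "benign" if core_type == "benign" else "cancer"
        models = {
            row["marker"]: MarkerModel(
                float(np.clip(row["alpha_true"], 0.0, 255.0)),
                latent_sd=0.0,
                noise_sd=0.0,
            )
            for _, row in sub.iterrows()
        }
        core_spec = TissueSimSpec(
            image_size=base.image_size,
            n_glands=base.n_glands,
            gland_radius=base.gland_radius,
            benign_fraction=1.0 if comp == "benign" else 0.0,
            marker_models={comp: models},
            rho={comp: 0.0},
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        image, truth = generate_tissue_core(core_spec)
        images.append((p, k, image, truth))
    return images
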