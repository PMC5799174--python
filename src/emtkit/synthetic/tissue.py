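"""Synthetic multiplex-IHC tissue cores with known compartment ground truth.

A core is a square 8-bit multi-channel image containing elliptical glands
(hard edges, no anti-aliasing) on a dark stromal background.  All glands are
panCK+; benign glands are additionally KRT5+ (the whole gland carries KRT5
so the truth labels {0 stroma, 1 benign/KRT5+, 2 cancer} match what the
panCK/KRT5 mask algebra recovers), while cancer glands are panCK+/KRT5-.
Marker channels (e.g. CAV1, ECADH) take a per-gland latent mean drawn from
a bivariate model that achieves the requested inter-marker correlation in
the latent means, plus i.i.d. pixel noise, then clip to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from ..types import MultiplexImage
from ._random import correlated_pair

COMPARTMENT_CODES = {"stroma": 0, "benign": 1, "cancer": 2}


@dataclass
class MarkerModel:
    """Per-compartment marker intensity model (all in 0-255 a.u.).

    ``mean`` and ``latent_sd`` describe the gland-to-gland latent level;
    ``noise_sd`` the per-pixel noise added on top of the gland latent.
    """

    mean: float
    latent_sd: float = 25.0
    noise_sd: float = 10.0

    def validate(self) -> None:
        if not 0.0 <= self.mean <= 255.0:
            raise ValueError(f"marker mean {self.mean} outside [0, 255]")
        if self.latent_sd < 0 or self.noise_sd < 0:
            raise ValueError("sds must be non-negative")


def _default_marker_models() -> Dict[str, Dict[str, MarkerModel]]:
    # Emulated effect structure: CAV1 higher and E-cadherin lower in cancer
    # than in benign epithelium, with inverse latent correlation in cancer
    # and weak positive correlation in benign glands.
    return {
        "benign": {
            "CAV1": MarkerModel(90.0),
            "ECADH": MarkerModel(150.0),
        },
        "cancer": {
            "CAV1": MarkerModel(140.0),
            "ECADH": MarkerModel(110.0),
        },
    }


@dataclass
class TissueSimSpec:
    """Study-condition parameters of the tissue-core generator."""

    image_size: int = 512
    n_glands: int = 12
    gland_radius: Tuple[float, float] = (18.0, 40.0)
    basal_ring_width: float = 4.0
    #: extra KRT5 intensity on the basal ring of benign glands (0 keeps the
    #: gland uniformly KRT5+, which zero-noise oracles rely on)
    krt5_ring_boost: float = 0.0
    benign_fraction: float = 0.5
    marker_models: Dict[str, Dict[str, MarkerModel]] = field(
        default_factory=_default_marker_models
    )
    #: target latent inter-marker correlation per compartment (first two
    #: markers of the compartment model); emulates the study's inverse
    #: cancer-compartment and weak positive benign-compartment association
    rho: Dict[str, float] = field(
        default_factory=lambda: {"benign": 0.14, "cancer": -0.35}
    )
    background_level: float = 0.0
    panck_mean: float = 180.0
    krt5_mean: float = 160.0
    hoechst_mean: float = 100.0
    structural_noise_sd: float = 0.0
    #: achieve rho exactly in the generated latent sample (see _random)
    empirical: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_glands < 1:
            raise ValueError("n_glands must be >= 1")
        for comp, markers in self.marker_models.items():
            for model in markers.values():
                model.validate()
        for comp, r in self.rho.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"|rho| must be <= 1 (compartment {comp})")


@dataclass
class TissueGroundTruth:
    """Truth for one core: label raster, per-gland latents, injected rho."""

    compartment_labels: np.ndarray  # {0 stroma, 1 benign, 2 cancer}
    glands: pd.DataFrame  # gland_id, compartment, area plus latent_<marker>
    rho: Dict[str, float]


def _place_glands(
    spec: TissueSimSpec, rng: np.random.Generator
) -> List[dict]:
    """Rejection-sample non-overlapping rotated ellipses inside the core."""
    glands: List[dict] = []
    r_lo, r_hi = spec.gland_radius
    tries = 0
    while len(glands) < spec.n_glands:
        tries += 1
        if tries > 200 * spec.n_glands:
            raise RuntimeError(
                "could not place glands; lower n_glands or gland_radius"
            )
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(0.7 * a, a)
        theta = rng.uniform(0, np.pi)
        margin = a + 2
        if 2 * margin >= spec.image_size:
            raise ValueError("gland_radius too large for image_size")
        r = rng.uniform(margin, spec.image_size - margin)
        c = rng.uniform(margin, spec.image_size - margin)
        if all(
            np.hypot(r - g["r"], c - g["c"]) > a + g["a"] + 2 for g in glands
        ):
            glands.append({"r": r, "c": c, "a": a, "b": b, "theta": theta})
    return glands


def generate_tissue_core(
    spec: TissueSimSpec,
) -> Tuple[MultiplexImage, TissueGroundTruth]:
    """Render one synthetic core plus its ground truth (deterministic in
    ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    glands = _place_glands(spec, rng)
    compartments = np.where(
        rng.random(len(glands)) < spec.benign_fraction, "benign", "cancer"
    )

    labels = np.zeros((size, size), dtype=np.uint8)
    gland_masks = []
    for g, comp in zip(glands, compartments):
        rr, cc = ellipse(
            g["r"], g["c"], g["a"], g["b"], shape=(size, size),
            rotation=g["theta"],
        )
        labels[rr, cc] = COMPARTMENT_CODES[comp]
        gland_masks.append((rr, cc))

    markers = sorted(
        {m for models in spec.marker_models.values() for m in models}
    )
    # latent gland means, correlated within compartment for the first two
    # modelled markers, independent for any further markers
    latent = {m: np.zeros(len(glands)) for m in markers}
    for comp in ("benign", "cancer"):
        idx = np.flatnonzero(compartments == comp)
        if idx.size == 0:
            continue
        models = spec.marker_models.get(comp, {})
        names = list(models)
        if len(names) >= 2:
            pair = correlated_pair(
                idx.size,
                (models[names[0]].mean, models[names[1]].mean),
                (models[names[0]].latent_sd, models[names[1]].latent_sd),
                spec.rho.get(comp, 0.0),
                rng,
                empirical=spec.empirical,
            )
            latent[names[0]][idx] = pair[:, 0]
            latent[names[1]][idx] = pair[:, 1]
            extra = names[2:]
        else:
            extra = names
        for name in extra:
            model = models[name]
            latent[name][idx] = model.mean + model.latent_sd * rng.standard_normal(
                idx.size
            )

    def render(base: np.ndarray, noise_sd: float) -> np.ndarray:
        if noise_sd > 0:
            base = base + noise_sd * rng.standard_normal(base.shape)
        return np.clip(np.rint(base), 0, 255).astype(np.uint8)

    channels: Dict[str, np.ndarray] = {}
    bg = float(spec.background_level)
    panck = np.full((size, size), bg)
    krt5 = np.full((size, size), bg)
    hoechst = np.full((size, size), bg)
    panck[labels > 0] = spec.panck_mean
    krt5[labels == 1] = spec.krt5_mean
    if spec.krt5_ring_boost > 0:
        w = spec.basal_ring_width
        for g, comp in zip(glands, compartments):
            if comp != "benign" or min(g["a"], g["b"]) <= w:
                continue
            rr, cc = ellipse(
                g["r"], g["c"], g["a"] - w, g["b"] - w, shape=(size, size),
                rotation=g["theta"],
            )
            inner = np.zeros((size, size), dtype=bool)
            inner[rr, cc] = True
            rr_o, cc_o = ellipse(
                g["r"], g["c"], g["a"], g["b"], shape=(size, size),
                rotation=g["theta"],
            )
            ring = np.zeros((size, size), dtype=bool)
            ring[rr_o, cc_o] = True
            ring &= ~inner
            krt5[ring] = spec.krt5_mean + spec.krt5_ring_boost
    hoechst[labels > 0] = spec.hoechst_mean
    channels["Hoechst"] = render(hoechst, spec.structural_noise_sd)
    channels["panCK"] = render(panck, spec.structural_noise_sd)
    channels["KRT5"] = render(krt5, spec.structural_noise_sd)

    for m in markers:
        raster = np.full((size, size), bg)
        for i, ((rr, cc), comp) in enumerate(zip(gland_masks, compartments)):
            if m in spec.marker_models.get(comp, {}):
                raster[rr, cc] = latent[m][i]
        noise_sds = {
            comp: spec.marker_models[comp][m].noise_sd
            for comp in spec.marker_models
            if m in spec.marker_models[comp]
        }
        # per-pixel noise may differ by compartment; render per compartment
        out = np.full((size, size), bg)
        out[:] = raster
        for comp, nsd in noise_sds.items():
            region = labels == COMPARTMENT_CODES[comp]
            if nsd > 0 and region.any():
                out[region] = raster[region] + nsd * rng.standard_normal(
                    int(region.sum())
                )
        channels[m] = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    rows = []
    for i, ((rr, cc), comp) in enumerate(zip(gland_masks, compartments)):
        row = {"gland_id": i, "compartment": comp, "area": len(rr)}
        for m in markers:
            row[f"latent_{m}"] = latent[m][i]
        rows.append(row)
    truth = TissueGroundTruth(
        compartment_labels=labels,
        glands=pd.DataFrame(rows),
        rho=dict(spec.rho),
    )
    return MultiplexImage(channels=channels), truth


def generate_region_set(
    n_regions: int,
    compartment: str,
    rho: float,
    marker_models: Optional[Dict[str, MarkerModel]] = None,
    region_size: int = 72,
    gland_radius: Tuple[float, float] = (18.0, 26.0),
    seed: int = 0,
    empirical: bool = True,
) -> Tuple[List[MultiplexImage], pd.DataFrame]:
    """Single-compartment image regions with region-level marker latents.

    Emulates the per-patient "representative image regions" of the TMA
    analysis: each region is a small core containing one gland of the given
    compartment whose two marker latents are drawn across regions from the
    bivariate model with the requested correlation.  Returns the rendered
    regions and a truth table (region_id, latent_<marker>).
    """
    if marker_models is None:
        marker_models = _default_marker_models()[compartment]
    names = list(marker_models)
    if len(names) != 2:
        raise ValueError("region set needs exactly two marker models")
    rng = np.random.default_rng(seed)
    latents = correlated_pair(
        n_regions,
        (marker_models[names[0]].mean, marker_models[names[1]].mean),
        (marker_models[names[0]].latent_sd, marker_models[names[1]].latent_sd),
        rho,
        rng,
        empirical=empirical,
    )
    images = []
    for i in range(n_regions):
        models = {
            names[0]: MarkerModel(
                np.clip(latents[i, 0], 0.0, 255.0),
                latent_sd=0.0,
                noise_sd=marker_models[names[0]].noise_sd,
            ),
            names[1]: MarkerModel(
                np.clip(latents[i, 1], 0.0, 255.0),
                latent_sd=0.0,
                noise_sd=marker_models[names[1]].noise_sd,
            ),
        }
        region_spec = TissueSimSpec(
            image_size=region_size,
            n_glands=1,
            gland_radius=gland_radius,
            benign_fraction=1.0 if compartment == "benign" else 0.0,
            marker_models={compartment: models},
            rho={compartment: 0.0},
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        image, _ = generate_tissue_core(region_spec)
        images.append(image)
    truth = pd.DataFrame(
        {
            "region_id": np.arange(n_regions),
            f"latent_{names[0]}": latents[:, 0],
            f"latent_{names[1]}": latents[:, 1],
        }
    )
    return images, truth
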