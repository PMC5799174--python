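import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_noise_core():
    """One all-cancer core rendered without noise: CAV1=200, ECADH=110."""
    from emtkit.synthetic import MarkerModel, TissueSimSpec, generate_tissue_core

    spec = TissueSimSpec(
        image_size=128,
        n_glands=3,
        gland_radius=(12, 20),
        benign_fraction=0.0,
        marker_models={
            "cancer": {
                "CAV1": MarkerModel(200, latent_sd=0, noise_sd=0),
                "ECADH": MarkerModel(110, latent_sd=0, noise_sd=0),
            }
        },
        rho={"cancer": 0.0},
        seed=1,
    )
    return generate_tissue_core(spec)


@pytest.fixture
def mixed_core():
    """Benign + cancer core, zero noise, default marker models."""
    from emtkit.synthetic import TissueSimSpec, generate_tissue_core

    spec = TissueSimSpec(
        image_size=256, n_glands=6, gland_radius=(14, 24), seed=3
    )
    for models in spec.marker_models.values():
        for m in models.values():
            m.noise_sd = 0.0
    return generate_tissue_core(spec)
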