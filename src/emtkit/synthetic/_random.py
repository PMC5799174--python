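"""Correlated-draw helpers for the generators."""

from __future__ import annotations

import numpy as np


def correlated_pair(
    n: int,
    means: tuple,
    sds: tuple,
    rho: float,
    rng: np.random.Generator,
    empirical: bool = True,
) -> np.ndarray:
    """Draw n bivariate-normal pairs with the requested correlation.

    With ``empirical=True`` (and n >= 3, |rho| < 1, non-zero spread) the
    sample is whitened and recoloured so the *sample* correlation of the
    returned latent values equals ``rho`` exactly, in the spirit of
    ``MASS::mvrnorm(empirical = TRUE)``; otherwise ``rho`` is the population
    correlation of the draw.  Degenerate cases (|rho| = 1, sd = 0) are
    constructed directly.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    mx, my = float(means[0]), float(means[1])
    sx, sy = float(sds[0]), float(sds[1])
    if sx < 0 or sy < 0:
        raise ValueError("latent sds must be non-negative")
    z = rng.standard_normal((n, 2))
    if sx == 0 or sy == 0:
        x = mx + sx * z[:, 0]
        y = my + sy * z[:, 1]
        return np.column_stack([x, y])
    if abs(rho) == 1.0:
        x = mx + sx * z[:, 0]
        y = my + np.sign(rho) * sy * z[:, 0]
        return np.column_stack([x, y])
    if empirical and n >= 3:
        zc = z - z.mean(axis=0)
        cov = np.cov(zc, rowvar=False)
        zw = zc @ np.linalg.inv(np.linalg.cholesky(cov).T)
        target = np.array([[1.0, rho], [rho, 1.0]])
        z = zw @ np.linalg.cholesky(target).T
    else:
        z = np.column_stack(
            [z[:, 0], rho * z[:, 0] + np.sqrt(1.0 - rho ** 2) * z[:, 1]]
        )
    return np.column_stack([mx + sx * z[:, 0], my + sy * z[:, 1]])
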