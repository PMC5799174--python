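"""Synthetic genes x samples expression matrices with known structure.

Emulates the statistical structure the expression workflow assumes: a log2
matrix over two sample classes (epithelial and mesenchymal, 35 vs 4 in the
emulated panel), a block of truly differential genes at a stated logFC, an
anchor gene (named CAV1, itself mesenchymal-up) whose co-expression block
shares a latent factor, and Absent/Marginal/Present detection flags tied to
expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass
class ExpressionSimSpec:
    n_genes: int = 2000
    n_epithelial: int = 35
    n_mesenchymal: int = 4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25  # log2 units
    de_fraction: float = 0.05
    logfc: float = 2.0  # log2 units, mesenchymal - epithelial
    #: fraction of mesenchymal-up genes additionally expressed (at half
    #: amplitude) in the first half of the epithelial panel ("transition"
    #: genes, opt-in); the epithelial dilution lowers their effective logFC
    #: to 0.75 * logfc
    transition_fraction: float = 0.0
    anchor_gene: str = "CAV1"
    anchor_block_size: int = 50
    anchor_rho: float = 0.9
    #: genes whose baseline falls in the lowest quantile get Absent flags
    flag_absent_quantile: float = 0.2
    flag_absent_prob: float = 0.9
    flag_marginal_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_epithelial < 2 or self.n_mesenchymal < 2:
            raise ValueError("need >= 2 samples per class")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.anchor_rho <= 1.0:
            raise ValueError("anchor_rho must be in [0, 1]")


def generate_expression_matrix(spec: ExpressionSimSpec) -> dict:
    """Generate matrix, flags and truth; deterministic in ``spec.seed``.

    Returns a dict with ``matrix`` (genes x samples, log2), ``flags``
    (same shape, {A, M, P}), ``labels`` (sample -> class) and ``truth``
    (up-/down-regulated gene lists and anchor-block membership).

    Construction: per-gene baseline ~ N(baseline_mean, baseline_sd); the
    first ``de_fraction * n_genes`` genes split evenly into mesenchymal-up
    and epithelial-up at +/- logfc (the anchor gene is always
    mesenchymal-up); anchor-block genes draw their noise as
    sqrt(rho) * shared factor + sqrt(1-rho) * idiosyncratic, both scaled to
    ``noise_sd``, so every pair of block genes (anchor included) has
    population correlation ``anchor_rho``.  When ``transition_fraction`` is
    set, the last such fraction of the up-regulated genes is additionally
    expressed at half amplitude in the first half of the epithelial
    samples, emulating genes that mark a transitional rather than a fully
    mesenchymal state.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_s = spec.n_epithelial + spec.n_mesenchymal
    samples = [f"EPI{i+1:03d}" for i in range(spec.n_epithelial)] + [
        f"MES{i+1:03d}" for i in range(spec.n_mesenchymal)
    ]
    labels = {
        s: ("epithelial" if s.startswith("EPI") else "mesenchymal")
        for s in samples
    }
    is_mes = np.array([labels[s] == "mesenchymal" for s in samples])

    n_de = int(round(spec.de_fraction * spec.n_genes))
    n_up = n_de // 2 + n_de % 2
    n_down = n_de - n_up
    genes = [f"G{i+1:05d}" for i in range(spec.n_genes)]
    up_idx = np.arange(0, n_up)
    down_idx = np.arange(n_up, n_up + n_down)

    # anchor block: the anchor gene plus block_size - 1 companions; the
    # anchor is the first up-regulated gene when any DE is injected
    anchor_idx = 0
    block = np.arange(anchor_idx, anchor_idx + spec.anchor_block_size)
    block = block[block < spec.n_genes]
    genes[anchor_idx] = spec.anchor_gene

    baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(
        spec.n_genes
    )
    effect = np.zeros(spec.n_genes)
    effect[up_idx] = spec.logfc
    effect[down_idx] = -spec.logfc

    on = np.tile(is_mes, (spec.n_genes, 1)).astype(float)
    n_trans = int(round(spec.transition_fraction * len(up_idx)))
    trans_idx = up_idx[len(up_idx) - n_trans:] if n_trans else up_idx[:0]
    if n_trans:
        half_epi = np.zeros(n_s, dtype=bool)
        half_epi[: spec.n_epithelial // 2] = True
        # half amplitude: a partial-EMT state, not full mesenchymal level
        on[np.ix_(trans_idx, np.flatnonzero(half_epi))] = 0.5
    x = baseline[:, None] + effect[:, None] * on
    noise = rng.standard_normal((spec.n_genes, n_s))
    if spec.anchor_rho > 0 and len(block) > 1:
        factor = rng.standard_normal(n_s)
        noise[block] = (
            np.sqrt(spec.anchor_rho) * factor[None, :]
            + np.sqrt(1.0 - spec.anchor_rho) * noise[block]
        )
    x = x + spec.noise_sd * noise

    matrix = pd.DataFrame(x, index=genes, columns=samples)

    q = np.quantile(baseline, spec.flag_absent_quantile)
    low = baseline <= q
    u = rng.random((spec.n_genes, n_s))
    flags = np.full((spec.n_genes, n_s), "P", dtype="<U1")
    flags[low[:, None] & (u < spec.flag_absent_prob)] = "A"
    flags[
        ~low[:, None] & (u < spec.flag_marginal_prob)
    ] = "M"
    flags = pd.DataFrame(flags, index=genes, columns=samples)

    truth = {
        "up_genes": [genes[i] for i in up_idx],
        "down_genes": [genes[i] for i in down_idx],
        "anchor_block": [genes[i] for i in block],
        "transition_genes": [genes[i] for i in trans_idx],
    }
    return {"matrix": matrix, "flags": flags, "labels": labels, "truth": truth}
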