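"""Synthetic RNAi screen plates with known knockdown effects.

The emulated design follows the image-based screen: three prostate cell
lines, three replicate plates per line, four siRNAs per gene, negative
(non-targeting) and positive control wells, and two read-out markers (CAV1
and ITGB1) quantified per cell.

Per-cell intensities are log-normal.  The regulatory hierarchy is wired in
explicitly: silencing ITGB1 lowers ITGB1 by the siRNA's efficiency and
lowers CAV1 through a coupling slope on the log scale (so CAV1 falls by a
factor (1-e)^coupling), whereas silencing CAV1 lowers CAV1 only.  The same
coupling acts on the per-cell latent ITGB1 deviation, which produces the
positive single-cell CAV1-ITGB1 correlation seen in control wells:
r_log = coupling*s_I / sqrt(coupling^2 s_I^2 + s_C^2), about 0.55 at the
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..types import MultiplexImage


@dataclass
class SiRNASpec:
    sirna_id: str
    efficiency: float  # knockdown fraction in [0, 1]

    def validate(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(
                f"knockdown efficiency must be in [0,1]: {self.sirna_id}"
            )


@dataclass
class GeneSpec:
    name: str
    sirnas: List[SiRNASpec]
    target_marker: Optional[str] = None  # None: no true effect (null gene)


@dataclass
class ScreenSimSpec:
    """Study-condition parameters of the screen generator."""

    genes: List[GeneSpec]
    #: log-scale slope of ITGB1 level into CAV1 level; 0.66 yields a
    #: control-well single-cell Pearson r of about 0.55
    coupling: float = 0.66
    cells_per_well: int = 500
    median_intensity: Dict[str, float] = field(
        default_factory=lambda: {"CAV1": 100.0, "ITGB1": 120.0}
    )
    cell_log_sd: Dict[str, float] = field(
        default_factory=lambda: {"CAV1": 0.35, "ITGB1": 0.35}
    )
    well_log_sd: float = 0.05  # multiplicative well-to-well variation
    n_replicates: int = 3
    neg_control_wells: int = 8
    pos_control_wells: int = 4
    pos_control_efficiency: float = 0.8
    cell_lines: Tuple[str, ...] = ("PC-3", "PNT2", "DU145")
    seed: int = 0

    def validate(self) -> None:
        if not self.genes:
            raise ValueError("empty gene list")
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.coupling < 0:
            raise ValueError(
                "negative coupling would drive intensities negative"
            )
        for g in self.genes:
            for s in g.sirnas:
                s.validate()


def default_screen_spec(
    n_null_genes: int = 20,
    efficiencies: Sequence[float] = (0.7, 0.75, 0.8, 0.85),
    seed: int = 0,
    **overrides,
) -> ScreenSimSpec:
    """The emulated screen: ITGB1 and CAV1 plus a panel of null genes, four
    siRNAs each."""

    def gene(name: str, target: Optional[str], effs: Sequence[float]) -> GeneSpec:
        return GeneSpec(
            name=name,
            sirnas=[
                SiRNASpec(f"si{name}_{i+1}", e) for i, e in enumerate(effs)
            ],
            target_marker=target,
        )

    genes = [gene("ITGB1", "ITGB1", efficiencies),
             gene("CAV1", "CAV1", efficiencies)]
    genes += [
        gene(f"NULL{i+1:02d}", None, [0.0] * len(efficiencies))
        for i in range(n_null_genes)
    ]
    return ScreenSimSpec(genes=genes, seed=seed, **overrides)


def _well_cells(
    spec: ScreenSimSpec,
    rng: np.random.Generator,
    kd: Dict[str, float],
) -> Dict[str, np.ndarray]:
    """Per-cell CAV1/ITGB1 intensities for one well under knockdowns
    ``kd`` (fraction removed per marker)."""
    n = spec.cells_per_well
    s_i = spec.cell_log_sd["ITGB1"]
    s_c = spec.cell_log_sd["CAV1"]
    e_i = s_i * rng.standard_normal(n) if s_i > 0 else np.zeros(n)
    e_c = s_c * rng.standard_normal(n) if s_c > 0 else np.zeros(n)
    w_i = spec.well_log_sd * rng.standard_normal() if spec.well_log_sd else 0.0
    w_c = spec.well_log_sd * rng.standard_normal() if spec.well_log_sd else 0.0
    with np.errstate(divide="ignore"):
        shift_i = np.log1p(-kd.get("ITGB1", 0.0))  # -inf at efficiency 1
        shift_c = np.log1p(-kd.get("CAV1", 0.0))
    itgb1 = np.exp(
        np.log(spec.median_intensity["ITGB1"]) + shift_i + w_i + e_i
    )
    cav1 = np.exp(
        np.log(spec.median_intensity["CAV1"])
        + spec.coupling * (shift_i + e_i)
        + shift_c
        + w_c
        + e_c
    )
    return {"ITGB1": itgb1, "CAV1": cav1}


def generate_screen_plate(spec: ScreenSimSpec) -> pd.DataFrame:
    """Ground-truth per-cell intensity table for the whole screen.

    One plate per (cell line, replicate); wells: one per (gene, siRNA),
    plus negative controls (non-targeting) and positive controls (both
    markers knocked down by ``pos_control_efficiency``).  Deterministic in
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for line in spec.cell_lines:
        for rep in range(1, spec.n_replicates + 1):
            plate = f"{line}_r{rep}"
            wells: List[tuple] = []
            for g in spec.genes:
                for s in g.sirnas:
                    kd = (
                        {g.target_marker: s.efficiency}
                        if g.target_marker
                        else {}
                    )
                    wells.append(("sample", g.name, s.sirna_id, kd))
            for i in range(spec.neg_control_wells):
                wells.append((f"neg_control", None, f"siCTRL_{i+1}", {}))
            e = spec.pos_control_efficiency
            for i in range(spec.pos_control_wells):
                wells.append(
                    ("pos_control", None, f"siPOS_{i+1}",
                     {"CAV1": e, "ITGB1": e})
                )
            for w, (role, gene, sirna, kd) in enumerate(wells):
                cells = _well_cells(spec, rng, kd)
                n = spec.cells_per_well
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_line": line,
                            "replicate": rep,
                            "plate": plate,
                            "well": f"W{w+1:03d}",
                            "well_role": role,
                            "gene": gene,
                            "sirna_id": sirna,
                            "cell_id": np.arange(n),
                            "CAV1": cells["CAV1"],
                            "ITGB1": cells["ITGB1"],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def generate_well_image(
    cells: pd.DataFrame,
    image_size: int = 256,
    nucleus_radius: int = 4,
    cell_radius: int = 9,
    markers: Sequence[str] = ("CAV1", "ITGB1"),
    hoechst_level: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[MultiplexImage, pd.DataFrame]:
    """Render one well: non-overlapping cell disks carrying per-cell marker
    intensity, nuclei disks on the Hoechst channel.

    Cells beyond what fits without overlap are dropped; the returned truth
    table lists the rendered cells with their centres and intensities so
    cell segmentation can be checked against construction.
    """
    rng = np.random.default_rng(seed)
    centres: List[Tuple[int, int]] = []
    margin = cell_radius + 1
    min_d = 2 * cell_radius + 2
    rendered_rows = []
    for _, row in cells.iterrows():
        placed = False
        for _ in range(200):
            r = rng.integers(margin, image_size - margin)
            c = rng.integers(margin, image_size - margin)
            if all(np.hypot(r - rr, c - cc) >= min_d for rr, cc in centres):
                centres.append((int(r), int(c)))
                rendered_rows.append(
                    {**row.to_dict(), "row": int(r), "col": int(c)}
                )
                placed = True
                break
        if not placed:
            break
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    hoechst = np.zeros((image_size, image_size))
    rasters = {m: np.zeros((image_size, image_size)) for m in markers}
    for row in rendered_rows:
        disk = (yy - row["row"]) ** 2 + (xx - row["col"]) ** 2
        hoechst[disk <= nucleus_radius ** 2] = hoechst_level
        cell_mask = disk <= cell_radius ** 2
        for m in markers:
            rasters[m][cell_mask] = row[m]
    channels = {"Hoechst": hoechst}
    channels.update(rasters)
    out = {}
    for name, raster in channels.items():
        if noise_sd > 0:
            raster = raster + noise_sd * rng.standard_normal(raster.shape)
        out[name] = np.clip(np.rint(raster), 0, 255).astype(np.uint8)
    return MultiplexImage(channels=out), pd.DataFrame(rendered_rows)
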