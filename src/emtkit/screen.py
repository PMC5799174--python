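"""Image-based RNAi screen analysis.

The screen read-out is a per-cell marker intensity table (from segmented
well images or a generator truth table).  Wells are summarised by their
median intensity, each sample well is z-scored against the negative-control
wells of its own replicate plate, and the per-siRNA score is the mean z over
replicates (three in the emulated design).  A gene's hit strength is the
number of its siRNAs with mean z above a threshold (strictly greater than
1.0 by default), counted per cell line.

Sign convention: z = (mu_ctrl - median_well) / sd_ctrl, so silencing that
*lowers* the read-out marker gives a positive z; genes called this way are
positive regulators of the read-out.  Control statistics use the sample
(n-1) standard deviation of control-well medians; a robust median/MAD
variant is available.

Assay quality is tracked by the Z'-factor
    z' = 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg|
on positive- vs negative-control well medians.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import StatResult, paired_correlation
from .types import DegenerateInputError

WELL_KEYS = ["cell_line", "replicate", "plate", "well"]
WELL_META = ["well_role", "gene", "sirna_id"]


def summarize_wells(cells: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    """Per-well median intensity per marker and cell count."""
    if cells.empty:
        raise DegenerateInputError("empty cell table")
    keys = [k for k in WELL_KEYS if k in cells.columns]
    meta = [m for m in WELL_META if m in cells.columns]
    agg = {m: (m, "median") for m in markers}
    out = cells.groupby(keys + meta, dropna=False, sort=True).agg(
        n_cells=("cell_id", "size"), **agg
    )
    return out.reset_index()


def compute_zscores(
    wells: pd.DataFrame,
    markers: Sequence[str],
    robust: bool = False,
) -> pd.DataFrame:
    """Replicate-plate z-scores of sample wells against negative controls.

    For every (cell line, replicate, plate) the negative-control well
    medians give mu_ctrl and sd_ctrl per marker; each sample well scores
    z = (mu_ctrl - median) / sd_ctrl.  With ``robust=True`` the centre is
    the control median and the scale 1.4826 * MAD.  Returns per-siRNA rows
    with per-replicate z and the across-replicate mean z per marker.
    """
    keys = [k for k in ("cell_line", "replicate", "plate") if k in wells.columns]
    plate_keys = [k for k in keys if k != "well"]
    scored = []
    for _, plate in wells.groupby(plate_keys, dropna=False):
        ctrl = plate[plate["well_role"] == "neg_control"]
        if len(ctrl) < 2:
            raise ValueError("need >= 2 negative-control wells per plate")
        sample = plate[plate["well_role"] == "sample"].copy()
        for m in markers:
            c = ctrl[m].to_numpy(dtype=float)
            if robust:
                mu, sd = np.median(c), 1.4826 * stats.median_abs_deviation(c)
            else:
                mu, sd = c.mean(), c.std(ddof=1)
            if sd == 0:
                raise DegenerateInputError(
                    f"control sd is zero for marker {m}; z undefined"
                )
            sample[f"z_{m}"] = (mu - sample[m].to_numpy(dtype=float)) / sd
        scored.append(sample)
    z = pd.concat(scored, ignore_index=True)
    group = [c for c in ("cell_line", "gene", "sirna_id") if c in z.columns]
    agg = {f"mean_z_{m}": (f"z_{m}", "mean") for m in markers}
    agg.update({f"median_{m}": (m, "mean") for m in markers})
    out = z.groupby(group, dropna=False).agg(
        n_replicates=("replicate", "nunique"), **agg
    )
    return out.reset_index()


def call_hits(
    results: pd.DataFrame,
    marker: str,
    threshold: float = 1.0,
    min_sirnas: int = 2,
    min_cell_lines: int = 1,
) -> pd.DataFrame:
    """Count siRNAs with mean z strictly above ``threshold`` per gene and
    cell line, and call regulators.

    A gene is called a regulator of the read-out marker when at least
    ``min_sirnas`` of its siRNAs score in at least ``min_cell_lines`` cell
    lines.
    """
    zcol = f"mean_z_{marker}"
    hits = (
        results.assign(hit=results[zcol] > threshold)
        .groupby(["gene", "cell_line"], dropna=False)
        .agg(n_sirnas=("sirna_id", "nunique"), sirna_hit_count=("hit", "sum"))
        .reset_index()
    )
    lines_ok = (
        hits.assign(line_ok=hits["sirna_hit_count"] >= min_sirnas)
        .groupby("gene")["line_ok"]
        .sum()
    )
    hits["regulator_call"] = hits["gene"].map(lines_ok >= min_cell_lines)
    return hits


def zprime(pos_controls: np.ndarray, neg_controls: np.ndarray) -> float:
    """Z'-factor assay-quality metric on control well medians."""
    pos = np.asarray(pos_controls, dtype=float)
    neg = np.asarray(neg_controls, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 wells in each control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise DegenerateInputError("equal control means: z' undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_p - mu_n))


def single_cell_marker_correlation(
    cells: pd.DataFrame, marker_x: str, marker_y: str
) -> dict:
    """Pearson r of per-cell intensities in control wells, per cell line."""
    out = {}
    for line, sub in cells.groupby("cell_line"):
        if len(sub) < 10:
            raise ValueError(f"need >= 10 cells per cell line (got {len(sub)})")
        out[line] = paired_correlation(
            sub[marker_x].to_numpy(), sub[marker_y].to_numpy(), method="pearson"
        )
    return out


def per_sirna_test(
    cells_sirna: np.ndarray, cells_ctrl: np.ndarray
) -> StatResult:
    """Two-sided Welch t-test of per-cell intensities, siRNA vs pooled
    controls."""
    a = np.asarray(cells_sirna, dtype=float)
    b = np.asarray(cells_ctrl, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 cells per sample")
    if np.array_equal(a, b):
        return StatResult(0.0, 1.0, "welch-t")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return StatResult(float(t), float(p), "welch-t")
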