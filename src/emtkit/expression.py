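"""Microarray-style expression workflow.

Implements the expression-signature chain: probe-to-gene summarisation by
one-step Tukey biweight, floor-and-quantile normalisation, the three-stage
probe filter (expression band, detection flags, coefficient of variation),
two-group differential expression with an empirical-Bayes moderated t and
Benjamini-Hochberg q-values, top-k epithelial/mesenchymal signature lists,
correlation-distance hierarchical sub-clustering of the mesenchymal
signature, PCA class separation, and anchor-gene co-expression ranking
(top-n genes with Pearson r above a floor).

Matrices are pandas DataFrames with genes in rows and samples in columns,
on the log2 scale after normalisation.  Detection flags, where present,
form an equally shaped DataFrame with entries in {"A", "M", "P"}
(Absent / Marginal / Present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .types import DegenerateInputError

FLAGS = ("A", "M", "P")

# One-step Tukey biweight constants: tuning constant and the floor added to
# the MAD so a zero spread never zeroes the scale.
TUKEY_C = 5.0
TUKEY_EPS = 1e-4


def tukey_biweight(values: np.ndarray, c: float = TUKEY_C,
                   eps: float = TUKEY_EPS) -> float:
    """One-step Tukey biweight location estimate.

    Distances from the median are scaled by c * MAD + eps; points beyond
    that get zero weight, the rest the biweight (1 - u^2)^2.  A single
    value is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.size == 1:
        return float(x[0])
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def summarize_probesets(
    probes: pd.DataFrame, gene_of_probe: Mapping[str, str]
) -> pd.DataFrame:
    """Combine probe rows mapping to one gene into a single per-gene value
    per sample using the Tukey biweight."""
    genes = probes.index.map(lambda p: gene_of_probe[p])
    return probes.groupby(genes).agg(lambda col: tukey_biweight(col.to_numpy()))


def quantile_normalize(matrix: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Floor values then force every sample to the mean order-statistic
    distribution.

    Each column's sorted values are replaced by the across-sample mean of
    order statistics; ties within a column receive the mean of their tied
    quantile targets, so ranks are preserved and every column's sorted
    vector is identical afterwards.  Idempotent.
    """
    x = matrix.to_numpy(dtype=float)
    x = np.maximum(x, floor)
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col = x[:, j]
        targets = np.empty(n)
        targets[order[:, j]] = reference
        # average targets over tied input values
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=targets)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    return np.log2(matrix)


def filter_probes(
    matrix: pd.DataFrame,
    flags: Optional[pd.DataFrame],
    conditions: Mapping[str, str],
    band: Tuple[float, float] = (20.0, 100.0),
    cv_min: float = 0.01,
    linear_scale_cv: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Sequential three-stage probe filter; returns the surviving matrix and
    the retention count after each stage.

    1. *By expression* — keep genes where, in at least one condition, every
       sample's value lies within that sample's [20th, 100th] percentile
       band of intensities.
    2. *By flags* — keep genes where, in at least one condition, every
       sample's flag is Present or Marginal.  Skipped when no flags given.
    3. *By error* — keep genes whose coefficient of variation across all
       samples exceeds ``cv_min`` (computed on the linear scale by default:
       on log2 data a 1% CV cut would remove almost nothing).
    """
    if flags is not None:
        bad = set(np.unique(flags.to_numpy())) - set(FLAGS)
        if bad:
            raise ValueError(f"unknown flag symbols: {sorted(bad)}")
    samples = list(matrix.columns)
    cond_of = {s: conditions[s] for s in samples}
    groups: Dict[str, List[str]] = {}
    for s, c in cond_of.items():
        groups.setdefault(c, []).append(s)

    counts: Dict[str, int] = {}
    lo = matrix.quantile(band[0] / 100.0, axis=0)
    hi = matrix.quantile(band[1] / 100.0, axis=0)
    in_band = (matrix.ge(lo, axis=1)) & (matrix.le(hi, axis=1))
    keep1 = np.zeros(len(matrix), dtype=bool)
    for cols in groups.values():
        keep1 |= in_band[cols].all(axis=1).to_numpy()
    matrix = matrix.loc[keep1]
    counts["expression"] = len(matrix)

    if flags is not None:
        reliable = flags.loc[matrix.index].isin(["P", "M"])
        keep2 = np.zeros(len(matrix), dtype=bool)
        for cols in groups.values():
            keep2 |= reliable[cols].all(axis=1).to_numpy()
        matrix = matrix.loc[keep2]
    counts["flags"] = len(matrix)

    values = matrix.to_numpy(dtype=float)
    if linear_scale_cv:
        values = np.power(2.0, values)
    cv = values.std(axis=1, ddof=1) / values.mean(axis=1)
    matrix = matrix.loc[cv > cv_min]
    counts["cv"] = len(matrix)
    return matrix, counts


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    _, q, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return q


def differential_expression(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    group_order: Optional[Tuple[str, str]] = None,
    q_max: float = 0.05,
    lfc_min: float = 1.5,
    moderated: bool = True,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Two-group differential expression with moderated t and BH q-values.

    logFC is the class-mean difference on the log2 scale, second group minus
    first in ``group_order`` (e.g. mesenchymal - epithelial, or treated -
    control).  The moderated statistic shrinks each gene's pooled variance
    toward the across-gene mean variance with weight ``prior_df`` (so a
    zero-variance gene never divides by zero) and refers the statistic to a
    t distribution with residual + prior degrees of freedom; ``moderated=
    False`` gives a plain Welch t-test instead.  A gene is ``selected`` when
    q < ``q_max`` and |logFC| > ``lfc_min``.
    """
    samples = list(matrix.columns)
    if group_order is None:
        group_order = tuple(dict.fromkeys(labels[s] for s in samples))  # type: ignore
    g0, g1 = group_order
    cols0 = [s for s in samples if labels[s] == g0]
    cols1 = [s for s in samples if labels[s] == g1]
    n0, n1 = len(cols0), len(cols1)
    if n0 < 2 or n1 < 2:
        raise ValueError("need >= 2 samples per class")
    a = matrix[cols0].to_numpy(dtype=float)
    b = matrix[cols1].to_numpy(dtype=float)
    logfc = b.mean(axis=1) - a.mean(axis=1)
    if moderated:
        df_res = n0 + n1 - 2
        pooled = (
            (n0 - 1) * a.var(axis=1, ddof=1) + (n1 - 1) * b.var(axis=1, ddof=1)
        ) / df_res
        s2_prior = pooled.mean()
        s2_post = (prior_df * s2_prior + df_res * pooled) / (prior_df + df_res)
        se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
        t = logfc / se
        df_total = df_res + prior_df
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    q = bh_qvalues(p)
    out = pd.DataFrame(
        {
            "gene": matrix.index,
            "logFC": logfc,
            "t": t,
            "p": p,
            "q": q,
        }
    ).set_index("gene")
    out["selected"] = (out["q"] < q_max) & (out["logFC"].abs() > lfc_min)
    return out


def rank_signatures(results: pd.DataFrame, k: int = 100) -> dict:
    """Top-k up-regulated (mesenchymal) and down-regulated (epithelial)
    signature lists by smallest p, ties broken by |logFC| then gene id."""
    def top(sub: pd.DataFrame) -> List[str]:
        sub = sub.assign(_abs=sub["logFC"].abs()).sort_values(
            by=["p", "_abs", "gene"], ascending=[True, False, True]
        )
        return sub["gene"].head(k).tolist()

    r = results.reset_index()
    mes = top(r[r["logFC"] > 0])
    epi = top(r[r["logFC"] < 0])
    return {
        "mesenchymal": mes,
        "epithelial": epi,
        "truncated": len(mes) < k or len(epi) < k,
    }


def hierarchical_clustering(
    matrix: pd.DataFrame,
    n_subclusters: int = 2,
    epithelial_samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Sub-cluster signature genes by 1 - Pearson correlation, average
    linkage.

    Returns per-gene cluster ids (1..n) and, when ``epithelial_samples`` is
    given, labels the sub-cluster with the higher mean expression across the
    epithelial samples "transition" and the other(s) "pure" — genes still
    expressed in part of the epithelial panel mark a transitional EMT state.
    Constant gene rows (undefined correlation) are dropped with a warning
    column rather than an error.
    """
    x = matrix.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    dropped = matrix.index[~keep]
    if len(dropped):
        import warnings

        warnings.warn(f"dropping {len(dropped)} constant gene rows")
    sub = matrix.loc[keep]
    if len(sub) < max(2, n_subclusters):
        raise ValueError("need at least max(2, n_subclusters) variable genes")
    if n_subclusters == 1:
        clusters = np.ones(len(sub), dtype=int)
    else:
        corr = np.corrcoef(sub.to_numpy(dtype=float))
        dist = 1.0 - corr[np.triu_indices(len(sub), k=1)]
        z = linkage(dist, method="average")
        clusters = fcluster(z, t=n_subclusters, criterion="maxclust")
    out = pd.DataFrame({"cluster": clusters}, index=sub.index)
    if epithelial_samples is not None:
        epi_mean = sub[list(epithelial_samples)].mean(axis=1)
        means = epi_mean.groupby(out["cluster"]).mean()
        transition = means.idxmax()
        out["label"] = np.where(
            out["cluster"] == transition, "transition", "pure"
        )
    return out


def pca_class_separation(
    matrix: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """PCA on gene-standardised data; returns sample coordinates on the
    leading components with class labels, for checking class separation on
    PC1."""
    from sklearn.decomposition import PCA

    x = matrix.to_numpy(dtype=float).T  # samples x genes
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    n_comp = min(5, x.shape[0] - 1, x.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    out = pd.DataFrame(
        pcs, index=matrix.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    out["label"] = [labels[s] for s in matrix.columns]
    return out


def anchor_coexpression(
    matrix: pd.DataFrame,
    anchor_gene: str,
    top_n: int = 500,
    r_min: float = 0.3,
) -> pd.DataFrame:
    """Rank genes by Pearson correlation with an anchor gene.

    Returns up to ``top_n`` genes with r > ``r_min`` sorted by decreasing r
    (the anchor itself, r = 1, ranks first).
    """
    if anchor_gene not in matrix.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    anchor = matrix.loc[anchor_gene].to_numpy(dtype=float)
    if np.ptp(anchor) == 0:
        raise DegenerateInputError("anchor gene is constant")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1)) * np.sqrt((ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ ac) / denom
    out = pd.DataFrame({"gene": matrix.index, "r": r}).dropna()
    out = out[out["r"] > r_min].sort_values(
        by=["r", "gene"], ascending=[False, True]
    )
    return out.head(top_n).reset_index(drop=True)
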