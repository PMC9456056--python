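"""Differential gene expression with the study's filtering rules.

Transcript counts are normalized per cell to counts-per-million on the log2
scale (a literal per-gene variant is available for fidelity experiments).
Genes are tested between two cell groups by a two-sided Wilcoxon rank-sum
test (exact enumeration when both groups have <= 8 cells, tie-corrected
normal approximation otherwise) with Benjamini-Hochberg adjustment, and the
usual companion statistics: avg_log2FC over de-logged means, and pct.1 /
pct.2 — the fraction of expressing cells in each group.

Filters: cluster markers keep adj_p < 0.05, avg_log2FC > 0 and
pct.1/pct.2 > 2.5; the condition-overlap set intersects genes upregulated
in both contrasts (e.g. CAD and DM) at adj_p < 0.05 with pct.1 > 0.2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats
from .matrix_io import CountMatrix, NormalizedMatrix

LFC_EPS = 1e-9


def normalize_genes(counts: CountMatrix, mode: str = "per_cell") -> NormalizedMatrix:
    """Log2 counts-per-million.

    ``per_cell`` (default): value = log2(1 + count * 1e6 / cell_total);
    invariant to uniform scaling of a cell's counts.  ``per_gene`` scales by
    each gene's total across cells instead.  Cells (or genes) with zero
    total map to 0 with a warning.
    """
    x = counts.counts.astype(float)
    if mode == "per_cell":
        totals = x.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            warnings.warn(f"{int((totals == 0).sum())} cell(s) with zero total counts",
                          stacklevel=2)
        values = np.log1p(x * 1e6 / np.where(totals > 0, totals, 1.0)) / np.log(2)
    elif mode == "per_gene":
        totals = x.sum(axis=0, keepdims=True)
        if (totals == 0).any():
            warnings.warn(f"{int((totals == 0).sum())} gene(s) with zero total counts",
                          stacklevel=2)
        values = np.log1p(x * 1e6 / np.where(totals > 0, totals, 1.0)) / np.log(2)
    else:
        raise ValueError("mode must be 'per_cell' or 'per_gene'")
    return NormalizedMatrix(counts.cells, counts.features, values, "per_million_log2")


def rank_sum_de(
    normalized: NormalizedMatrix | pd.DataFrame,
    group1_cells,
    group2_cells,
) -> pd.DataFrame:
    """Per-gene two-group DE table (gene, avg_log2FC, p_value, adj_p_value, pct1, pct2).

    avg_log2FC = log2((mean(2^v - 1) + eps) / (mean(2^v - 1) + eps)) over the
    normalized values v of each group; pct = fraction of cells with nonzero
    expression.  Constant genes get p = 1 and constant=True.
    """
    df = normalized.to_frame() if isinstance(normalized, NormalizedMatrix) else normalized
    a = df.loc[list(group1_cells)].to_numpy(dtype=float)
    b = df.loc[list(group2_cells)].to_numpy(dtype=float)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("both groups need at least 3 cells")
    m1 = np.expm1(a * np.log(2)).mean(axis=0)
    m2 = np.expm1(b * np.log(2)).mean(axis=0)
    lfc = np.log2((m1 + LFC_EPS) / (m2 + LFC_EPS))
    pct1 = (a > 0).mean(axis=0)
    pct2 = (b > 0).mean(axis=0)
    p = stats.ranksum_p_matrix(a, b)
    const = np.ptp(np.vstack([a, b]), axis=0) == 0
    out = pd.DataFrame(
        {
            "gene": df.columns,
            "avg_log2FC": lfc,
            "p_value": p,
            "adj_p_value": stats.bh_adjust(p),
            "pct1": pct1,
            "pct2": pct2,
            "constant": const,
        }
    )
    return out


def filter_cluster_markers(
    rows: pd.DataFrame,
    alpha: float = 0.05,
    pct_ratio: float = 2.5,
) -> pd.DataFrame:
    """Marker filter: adj_p < alpha, avg_log2FC > 0, pct1/pct2 > pct_ratio.

    pct2 = 0 counts as an infinite ratio when pct1 > 0.
    """
    pct2 = rows["pct2"].to_numpy(dtype=float)
    pct1 = rows["pct1"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pct2 > 0, pct1 / np.where(pct2 > 0, pct2, 1.0),
                         np.where(pct1 > 0, np.inf, 0.0))
    keep = (
        (rows["adj_p_value"] < alpha)
        & (rows["avg_log2FC"] > 0)
        & (ratio > pct_ratio)
    )
    return rows[keep].reset_index(drop=True)


def find_cluster_markers(
    normalized: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    pct_ratio: float = 2.5,
) -> pd.DataFrame:
    """One-vs-rest marker tables for every cluster, filtered."""
    df = normalized.to_frame() if isinstance(normalized, NormalizedMatrix) else normalized
    frames = []
    for cluster in sorted(labels.unique()):
        in_c = labels.index[labels == cluster]
        rest = labels.index[labels != cluster]
        if len(in_c) < 3 or len(rest) < 3:
            continue
        rows = rank_sum_de(df, in_c, rest)
        rows.insert(0, "cluster_id", cluster)
        frames.append(filter_cluster_markers(rows, alpha=alpha, pct_ratio=pct_ratio))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def condition_overlap(
    up_in_a: pd.DataFrame,
    up_in_b: pd.DataFrame,
    min_pct1: float = 0.2,
    alpha: float = 0.05,
) -> list[str]:
    """Genes significantly upregulated in BOTH contrasts.

    Keeps genes with adj_p < alpha, avg_log2FC > 0, pct1 > min_pct1 in each
    table, then intersects.
    """

    def up_set(rows: pd.DataFrame) -> set[str]:
        keep = (
            (rows["adj_p_value"] < alpha)
            & (rows["avg_log2FC"] > 0)
            & (rows["pct1"] > min_pct1)
        )
        return set(rows.loc[keep, "gene"])

    return sorted(up_set(up_in_a) & up_set(up_in_b))
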