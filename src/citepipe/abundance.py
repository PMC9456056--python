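"""Cluster-composition analysis: per-subject proportions, log-odds, tests.

For each subject, a cluster's abundance is expressed as the log-odds
ln(p/(1-p)) of its proportion p among the subject's cells of the parent
type, with Haldane-style pseudocount smoothing p' = (x+c)/(n+2c) so that
clusters absent from a subject stay finite.  Groups (e.g. CAD+ vs CAD-) are
compared per cluster by a two-sided rank-sum test on the subject-level
log-odds (exact enumeration when both groups have <= 8 subjects), with
Benjamini-Hochberg adjustment across clusters reported alongside raw p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats


@dataclass
class CompositionResult:
    per_subject: pd.DataFrame  # subject_id, cluster_id, n_cells, n_total, proportion, log_odds
    tests: pd.DataFrame  # cluster_id, group_a, group_b, statistic, p_value, adj_p_value


def compose(annotation: pd.DataFrame, within: str = "CD4T") -> pd.DataFrame:
    """Subject x cluster contingency counts among cells of the parent type.

    Uses clustered cells only; subjects without any clustered cell of the
    parent type are dropped with a warning.  Absent (subject, cluster)
    combinations are recorded as zero, not missing.
    """
    cells = annotation[
        (annotation["major_type"] == within)
        & annotation["cluster_id"].notna()
        & annotation["subject_id"].notna()
    ]
    if cells.empty:
        raise ValueError(f"no clustered {within} cells")
    table = (
        cells.groupby(["subject_id", "cluster_id"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    all_subjects = set(annotation["subject_id"].dropna())
    dropped = all_subjects - set(table.index)
    if dropped:
        warnings.warn(
            f"{len(dropped)} subject(s) with no clustered {within} cells dropped: "
            f"{sorted(dropped)}", stacklevel=2)
    return table


def log_odds(x: float, n: float, pseudocount: float = 0.5) -> float:
    """Natural-log odds of the smoothed proportion (x+c)/(n+2c)."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = (x + pseudocount) / (n + 2 * pseudocount)
    if not 0 < p < 1:
        raise ValueError("proportion outside (0, 1); use a positive pseudocount")
    return math.log(p / (1 - p))


def log_odds_table(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Subject x cluster log-odds from a contingency table."""
    n = counts.sum(axis=1).to_numpy(dtype=float)[:, None]
    x = counts.to_numpy(dtype=float)
    p = (x + pseudocount) / (n + 2 * pseudocount)
    return pd.DataFrame(np.log(p / (1 - p)), index=counts.index, columns=counts.columns)


def compare_composition(
    logodds: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-cluster two-sided rank-sum test of subject log-odds between groups."""
    groups = groups.reindex(logodds.index)
    idx_a = logodds.index[groups == group_a]
    idx_b = logodds.index[groups == group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"need >= 2 subjects per group ({group_a}: {len(idx_a)}, {group_b}: {len(idx_b)})"
        )
    rows = []
    for cluster in logodds.columns:
        a = logodds.loc[idx_a, cluster].to_numpy()
        b = logodds.loc[idx_b, cluster].to_numpy()
        stat, p = stats.ranksum_p(a, b)
        rows.append(
            {
                "cluster_id": cluster,
                "group_a": group_a,
                "group_b": group_b,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "statistic": stat,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p_value"] = stats.bh_adjust(out["p_value"])
    return out


def composition_analysis(
    annotation: pd.DataFrame,
    metadata: pd.DataFrame,
    group_column: str,
    group_a: str,
    group_b: str,
    within: str = "CD4T",
    pseudocount: float = 0.5,
) -> CompositionResult:
    """Counts -> proportions -> log-odds -> group tests, in one call."""
    counts = compose(annotation, within=within)
    n_total = counts.sum(axis=1)
    lo = log_odds_table(counts, pseudocount)
    per_subject = (
        counts.stack()
        .rename("n_cells")
        .reset_index()
        .rename(columns={"level_1": "cluster_id"})
    )
    per_subject["n_total"] = per_subject["subject_id"].map(n_total)
    per_subject["proportion"] = per_subject["n_cells"] / per_subject["n_total"]
    per_subject["log_odds"] = [
        lo.loc[s, c] for s, c in zip(per_subject["subject_id"], per_subject["cluster_id"])
    ]
    groups = metadata[group_column]
    tests = compare_composition(lo, groups, group_a, group_b)
    return CompositionResult(per_subject, tests)
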