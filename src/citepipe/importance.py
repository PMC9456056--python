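"""Iterated random-forest gene importance.

A random forest classifier is trained to separate two condition groups from
normalized gene expression of an equal subsample of cells per condition
(1000 by default).  Impurity-based variable importances from each of 15
iterations are min-max scaled to the 0-100 range; genes are ranked by the
mean scaled importance across iterations.  Rankings from two strata (e.g.
males vs females) are compared by Spearman correlation over the union of
either stratum's top-k genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .matrix_io import ImportanceParams, NormalizedMatrix


@dataclass
class ImportanceTable:
    scores: pd.DataFrame  # gene x iteration scaled importances in [0, 100]
    mean_importance: pd.Series
    rank: pd.Series  # 1 = most important; a permutation of 1..n_genes


def _sub_seed(master_seed: int, iteration: int) -> int:
    """Deterministic per-iteration seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, iteration]).generate_state(1)[0] % (2**31))


def iterated_importance(
    normalized: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    params: ImportanceParams | None = None,
    seed: int | None = None,
) -> ImportanceTable:
    """Repeatedly subsample, fit a forest, and aggregate scaled importances."""
    params = params or ImportanceParams()
    master = params.seed if seed is None else seed
    df = normalized.to_frame() if isinstance(normalized, NormalizedMatrix) else normalized
    labels = labels.reindex(df.index).dropna()
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two conditions, got {classes}")
    by_class = {c: labels.index[labels == c].to_numpy() for c in classes}
    for c, cells in by_class.items():
        if len(cells) < params.cells_per_condition:
            warnings.warn(
                f"condition {c!r} has {len(cells)} cells < "
                f"{params.cells_per_condition}; sampling with replacement",
                stacklevel=2)
    cols = {}
    for it in range(params.n_iterations):
        sub = _sub_seed(master, it)
        rng = np.random.default_rng(sub)
        take = np.concatenate(
            [
                rng.choice(cells, size=params.cells_per_condition,
                           replace=len(cells) < params.cells_per_condition)
                for c, cells in by_class.items()
            ]
        )
        x = df.loc[take].to_numpy(dtype=float)
        y = labels.loc[take].to_numpy()
        forest = RandomForestClassifier(
            n_estimators=params.n_trees, random_state=sub, n_jobs=1
        ).fit(x, y)
        imp = forest.feature_importances_
        span = imp.max() - imp.min()
        if span <= 0:
            warnings.warn(f"iteration {it}: degenerate (flat) importances", stacklevel=2)
            scaled = np.zeros_like(imp)
        else:
            scaled = (imp - imp.min()) / span * 100.0
        cols[f"iter_{it + 1}"] = scaled
    scores = pd.DataFrame(cols, index=pd.Index(df.columns, name="gene"))
    mean_imp = scores.mean(axis=1).rename("mean_importance")
    order = np.argsort(-mean_imp.to_numpy(), kind="stable")
    rank = pd.Series(0, index=mean_imp.index, name="rank")
    rank.iloc[order] = np.arange(1, len(rank) + 1)
    return ImportanceTable(scores, mean_imp, rank)


@dataclass
class RankComparison:
    pairs: pd.DataFrame  # gene, rank_a, rank_b, in_top_k, category
    correlation: float  # Spearman over the union set


def compare_ranks(
    table_a: ImportanceTable,
    table_b: ImportanceTable,
    top_k: int = 50,
    stratum_a: str = "A",
    stratum_b: str = "B",
) -> RankComparison:
    """Pair ranks for genes in either stratum's top-k; Spearman over the union.

    Genes outside the top-k in one stratum keep their actual rank there
    (``in_top_k`` records where each gene qualified).  Per-gene category:
    which stratum ranks the gene higher (lower rank number), or tied.
    """
    shared = table_a.rank.index.intersection(table_b.rank.index)
    if len(shared) < len(table_a.rank) or len(shared) < len(table_b.rank):
        warnings.warn("gene universes differ; restricting to intersection", stacklevel=2)
    ra = table_a.rank.loc[shared]
    rb = table_b.rank.loc[shared]
    union = shared[(ra <= top_k) | (rb <= top_k)]
    if len(union) == 0:
        raise ValueError("no genes in either top-k")
    cat = np.where(
        ra.loc[union] < rb.loc[union], f"{stratum_a}-higher",
        np.where(ra.loc[union] > rb.loc[union], f"{stratum_b}-higher", "tied"),
    )
    pairs = pd.DataFrame(
        {
            "gene": union,
            f"rank_{stratum_a}": ra.loc[union].to_numpy(),
            f"rank_{stratum_b}": rb.loc[union].to_numpy(),
            "in_top_k": np.where(
                (ra.loc[union] <= top_k) & (rb.loc[union] <= top_k), "both",
                np.where(ra.loc[union] <= top_k, stratum_a, stratum_b),
            ),
            "category": cat,
        }
    )
    if len(union) < 2 or (ra.loc[union].nunique() == 1 and rb.loc[union].nunique() == 1):
        corr = 1.0 if (ra.loc[union] == rb.loc[union]).all() else float("nan")
    else:
        corr = float(sps.spearmanr(ra.loc[union], rb.loc[union]).statistic)
    return RankComparison(pairs, corr)
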