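"""Surface-marker clustering of gated cells and rule-based phenotype naming.

Cells are clustered on their CLR-normalized antibody values (lineage markers
used for gating, e.g. CD19 and CD8 on CD4 T cells, are excluded): principal
components -> k-nearest-neighbor graph -> Louvain community detection at a
fixed resolution and seed.  Clusters are then named by memory/functional
phenotype rules over marker-positive fractions (Cm = CD45RA-CD197+,
Em = CD45RA-CD197-, Emra = CD45RA+CD197-, with optional distinguishing
markers such as CCR2).
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix_io import ClusteringParams, NormalizedMatrix


@dataclass
class ClusterResult:
    labels: pd.Series  # per-cell cluster id, contiguous from 1
    sizes: pd.Series  # per-cluster cell count
    positive_fraction: pd.DataFrame | None  # cluster x marker
    embedding: pd.DataFrame  # cells x (dim1, dim2)
    phenotypes: pd.Series | None = None  # per-cluster name, set by label_phenotypes


def embed_and_cluster(
    normalized: NormalizedMatrix | pd.DataFrame,
    config: ClusteringParams | None = None,
    exclude_features: tuple[str, ...] = (),
    precomputed_embedding: np.ndarray | None = None,
) -> ClusterResult:
    """PCA -> kNN graph -> Louvain communities at fixed resolution and seed.

    ``precomputed_embedding`` (cells x dims) bypasses the internal PCA, e.g.
    for an externally batch-corrected embedding.  Identical input and seed
    give identical labels.
    """
    config = config or ClusteringParams()
    df = normalized.to_frame() if isinstance(normalized, NormalizedMatrix) else normalized
    df = df.drop(columns=[c for c in exclude_features if c in df.columns])
    n_cells = len(df)
    if n_cells < 100:
        raise ValueError(f"need at least 100 cells to cluster, got {n_cells}")
    if n_cells <= config.knn_k:
        raise ValueError(
            f"{n_cells} cells but knn_k={config.knn_k}; choose a smaller k"
        )
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if precomputed_embedding is not None:
        pcs = np.asarray(precomputed_embedding, dtype=float)
        if pcs.shape[0] != n_cells:
            raise ValueError("precomputed embedding row count mismatch")
    elif np.allclose(x, 0):
        # degenerate: all cells identical -> single cluster
        labels = pd.Series(1, index=df.index, name="cluster_id")
        emb = pd.DataFrame(0.0, index=df.index, columns=["dim1", "dim2"])
        return ClusterResult(labels, labels.value_counts().sort_index(), None, emb)
    else:
        n_pcs = min(config.n_pcs, x.shape[1] - 1 if x.shape[1] > 1 else 1, n_cells - 1)
        pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
    nn = NearestNeighbors(n_neighbors=config.knn_k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    src = np.repeat(np.arange(n_cells), config.knn_k)
    dst = idx[:, 1:].ravel()  # drop self-neighbor
    edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst)}
    graph = igraph.Graph(n=n_cells, edges=sorted(edges))
    _random.seed(config.seed)
    communities = graph.community_multilevel(resolution=config.resolution)
    raw = np.asarray(communities.membership)
    # relabel 1..K by decreasing size, ties by first cell index (deterministic)
    order = sorted(
        set(raw), key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0]))
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=df.index, name="cluster_id")
    emb = pd.DataFrame(pcs[:, :2], index=df.index, columns=["dim1", "dim2"])
    return ClusterResult(labels, labels.value_counts().sort_index(), None, emb)


def positive_fractions(
    labels: pd.Series, positivity: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster fraction of marker-positive cells (cluster x marker)."""
    return positivity.loc[labels.index].groupby(labels).mean()


@dataclass(frozen=True)
class PhenotypeRule:
    name: str
    pattern: tuple[tuple[str, str], ...]  # (marker, '+' or '-') pairs

    def __post_init__(self) -> None:
        for _, sign in self.pattern:
            if sign not in "+-":
                raise ValueError("pattern signs must be '+' or '-'")


#: memory phenotype rules; more specific rules precede plain Em/Cm
DEFAULT_PHENOTYPE_RULES: list[PhenotypeRule] = [
    PhenotypeRule("Em CCR2+", (("CD45RA", "-"), ("CD197", "-"), ("CCR2", "+"))),
    PhenotypeRule("Cm", (("CD45RA", "-"), ("CD197", "+"))),
    PhenotypeRule("Em", (("CD45RA", "-"), ("CD197", "-"))),
    PhenotypeRule("Emra", (("CD45RA", "+"), ("CD197", "-"))),
    PhenotypeRule("Naive", (("CD45RA", "+"), ("CD197", "+"))),
]


def label_phenotypes(
    result: ClusterResult,
    positive_fraction: pd.DataFrame,
    rules: list[PhenotypeRule] | None = None,
    positivity_cutoff: float = 0.5,
) -> pd.Series:
    """Name clusters by the first matching phenotype rule.

    A cluster is marker-positive when its positive fraction strictly exceeds
    ``positivity_cutoff``; unmatched clusters get "Unlabeled-<id>".
    """
    rules = DEFAULT_PHENOTYPE_RULES if rules is None else rules
    for rule in rules:
        for marker, _ in rule.pattern:
            if marker not in positive_fraction.columns:
                raise KeyError(f"rule {rule.name!r} references unknown marker {marker!r}")
    names = {}
    for cluster in positive_fraction.index:
        name = f"Unlabeled-{cluster}"
        for rule in rules:
            ok = True
            for marker, sign in rule.pattern:
                positive = positive_fraction.loc[cluster, marker] > positivity_cutoff
                if (sign == "+") != bool(positive):
                    ok = False
                    break
            if ok:
                name = rule.name
                break
        names[cluster] = name
    out = pd.Series(names, name="phenotype_name")
    result.positive_fraction = positive_fraction
    result.phenotypes = out
    return out
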