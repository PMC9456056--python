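"""Core data model and plain-text IO.

Every stage of the pipeline exchanges three kinds of objects: integer UMI
count matrices (antibody tags, transcripts, or sample tags) over a shared
cell-barcode index, per-cell annotations accumulated along the pipeline, and
a flat configuration object holding every tunable.

Matrices are stored cells x features.  Two on-disk dialects are supported and
load to value-identical objects: Matrix Market (``.mtx`` with sidecar
``barcodes.tsv`` / ``features.tsv``, entries 1-based, rows = cells) and dense
CSV (header row = feature names, first column = barcodes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

MODALITIES = ("antibody", "gene", "tag")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass
class CountMatrix:
    """Raw UMI counts for one modality, cells x features."""

    cells: np.ndarray
    features: np.ndarray
    counts: np.ndarray  # dense int64, cells x features
    modality: str

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.features = np.asarray(self.features, dtype=object)
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise FormatError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("count matrix contains negative entries")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes")
        if len(set(self.features)) != len(self.features):
            raise FormatError("duplicate feature identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cells, columns=self.features)

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        idx = pd.Index(self.cells).get_indexer(list(barcodes))
        if (idx < 0).any():
            raise KeyError("barcode(s) not present in matrix")
        return CountMatrix(
            np.asarray(list(barcodes), dtype=object),
            self.features.copy(),
            self.counts[idx],
            self.modality,
        )


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized values, same shape as the source counts."""

    cells: np.ndarray
    features: np.ndarray
    values: np.ndarray
    normalization: str  # clr_log2 | per_million_log2

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.features = np.asarray(self.features, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("normalized matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.features)


TAG_CALLS = ("singlet", "multiplet", "undetermined")
MAJOR_TYPES = ("CD4T", "CD8T", "B", "Monocyte", "Other", "Unassigned")
DOUBLET_FLAGS = ("tag_multiplet", "expression_doublet", "biological_doublet")


def empty_annotation(barcodes: Sequence[str]) -> pd.DataFrame:
    """Fresh per-cell annotation table.

    Columns: subject_id (nullable str), plate_id, tag_call, the three doublet
    flag booleans, major_type, cluster_id (nullable int), phenotype_name.
    """
    n = len(barcodes)
    return pd.DataFrame(
        {
            "subject_id": pd.array([pd.NA] * n, dtype="string"),
            "plate_id": pd.array([pd.NA] * n, dtype="string"),
            "tag_call": pd.array(["undetermined"] * n, dtype="string"),
            "tag_multiplet": np.zeros(n, dtype=bool),
            "expression_doublet": np.zeros(n, dtype=bool),
            "biological_doublet": np.zeros(n, dtype=bool),
            "major_type": pd.array(["Unassigned"] * n, dtype="string"),
            "cluster_id": pd.array([pd.NA] * n, dtype="Int64"),
            "phenotype_name": pd.array([pd.NA] * n, dtype="string"),
        },
        index=pd.Index(barcodes, name="barcode"),
    )


def validate_annotation(ann: pd.DataFrame) -> None:
    bad = ~ann["tag_call"].isin(TAG_CALLS)
    if bad.any():
        raise ValueError(f"invalid tag_call values: {set(ann.loc[bad, 'tag_call'])}")
    singlet = ann["tag_call"] == "singlet"
    if ann.loc[singlet, "subject_id"].isna().any():
        raise ValueError("singlet cells must carry a subject_id")
    if ann.loc[~singlet, "subject_id"].notna().any():
        raise ValueError("non-singlet cells must not carry a subject_id")


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class MixtureParams:
    max_iter: int = 500
    tol: float = 1e-6
    n_init: int = 5

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.n_init < 1 or not 0 < self.tol < 1:
            raise ValueError("invalid mixture parameters")


@dataclass
class TagParams:
    min_count: int = 10
    dominance_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.dominance_ratio < 1:
            raise ValueError("dominance_ratio must be >= 1")


@dataclass
class ClusteringParams:
    n_pcs: int = 20
    resolution: float = 0.15
    seed: int = 42
    knn_k: int = 30
    embedding: str = "pca"  # pca | umap

    def __post_init__(self) -> None:
        if self.n_pcs < 1 or self.knn_k < 1 or self.resolution <= 0:
            raise ValueError("invalid clustering parameters")


@dataclass
class DGEParams:
    alpha: float = 0.05
    min_pct1: float = 0.2
    marker_pct_ratio: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 <= self.min_pct1 <= 1:
            raise ValueError("invalid DGE parameters")


@dataclass
class ImportanceParams:
    cells_per_condition: int = 1000
    n_iterations: int = 15
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cells_per_condition, self.n_iterations, self.n_trees) < 1:
            raise ValueError("invalid importance parameters")


#: stenosis lower bound (percent) -> base severity score
DEFAULT_GENSINI_MAPPING: dict[int, int] = {25: 1, 50: 2, 75: 4, 90: 8, 99: 16, 100: 32}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults."""

    clr_pseudocount: float = 1.0
    abundance_pseudocount: float = 0.5
    mixture: MixtureParams = field(default_factory=MixtureParams)
    tag: TagParams = field(default_factory=TagParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    dge: DGEParams = field(default_factory=DGEParams)
    importance: ImportanceParams = field(default_factory=ImportanceParams)
    gensini_mapping: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_GENSINI_MAPPING)
    )

    def __post_init__(self) -> None:
        if self.clr_pseudocount <= 0:
            raise ValueError("clr_pseudocount must be > 0")
        if self.abundance_pseudocount < 0:
            raise ValueError("abundance_pseudocount must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gensini_mapping"] = {int(k): int(v) for k, v in d["gensini_mapping"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sub = {
            "mixture": MixtureParams,
            "tag": TagParams,
            "clustering": ClusteringParams,
            "dge": DGEParams,
            "importance": ImportanceParams,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                extra = set(d[key]) - {f.name for f in dataclasses.fields(typ)}
                if extra:
                    raise ValueError(f"unknown keys in {key}: {sorted(extra)}")
                d[key] = typ(**d[key])
        if "gensini_mapping" in d:
            d["gensini_mapping"] = {int(k): int(v) for k, v in d["gensini_mapping"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Readers / writers

def read_count_matrix(path: str | Path, modality: str) -> CountMatrix:
    """Load a count matrix from MTX (+ sidecars) or dense CSV.

    ``path`` ending in ``.mtx`` expects ``barcodes.tsv`` and ``features.tsv``
    next to it; entries follow the 1-based Matrix Market convention with rows
    indexing cells.  Any other extension is parsed as dense CSV with feature
    names in the header and barcodes in the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise FormatError(f"{path}: malformed Matrix Market file: {exc}") from exc
        barcodes = _read_sidecar(path.parent / "barcodes.tsv")
        features = _read_sidecar(path.parent / "features.tsv")
        counts = np.asarray(sparse.coo_matrix(mat).todense())
        if counts.shape != (len(barcodes), len(features)):
            raise FormatError(
                f"{path}: matrix is {counts.shape} but sidecars list "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        return CountMatrix(barcodes, features, counts, modality)
    df = pd.read_csv(path, index_col=0)
    if df.columns.size == 0:
        raise FormatError(f"{path}: missing feature header row")
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().to_numpy().argmax()) + 2  # +header +1-based
            raise FormatError(f"{path}: non-numeric entry in column {col!r}, line {row}")
        df[col] = vals
    return CountMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        df.to_numpy(),
        modality,
    )


def _read_sidecar(path: Path) -> np.ndarray:
    if not path.exists():
        raise FormatError(f"missing sidecar file {path}")
    names = [line.split("\t")[0] for line in path.read_text().splitlines() if line]
    return np.asarray(names, dtype=object)


def write_count_matrix_mtx(mat: CountMatrix, directory: str | Path, name: str = "matrix") -> Path:
    """Write MTX + barcodes.tsv/features.tsv (cells x features orientation)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{name}.mtx"
    spio.mmwrite(out, sparse.coo_matrix(mat.counts), field="integer")
    (directory / "barcodes.tsv").write_text("\n".join(map(str, mat.cells)) + "\n")
    (directory / "features.tsv").write_text("\n".join(map(str, mat.features)) + "\n")
    return out


def write_count_matrix_csv(mat: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat.to_frame().to_csv(path, index_label="barcode")
    return path


def write_table(result: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as CSV with full round-trip precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = result if isinstance(result, pd.DataFrame) else pd.DataFrame(result)
    df.to_csv(path, index=bool(df.index.name))
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col, float_precision="round_trip")


def align_cells(*matrices: CountMatrix) -> list[CountMatrix]:
    """Restrict matrices to their shared barcodes (join key across modalities)."""
    common = pd.Index(matrices[0].cells)
    for m in matrices[1:]:
        common = common.intersection(pd.Index(m.cells))
    dropped = sum(len(m.cells) - len(common) for m in matrices)
    if dropped:
        logger.info("align_cells: dropped %d barcode entries missing in some modality", dropped)
    return [m.subset_cells(list(common)) for m in matrices]
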