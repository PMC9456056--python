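"""Sample-tag demultiplexing and doublet flagging.

Cells are hash-tagged per subject (four subjects multiplexed per plate); a
cell's subject is read off its dominant sample-tag.  The call rule is a
min-count plus dominance-ratio contract:

* undetermined — no tag reaches ``min_count``;
* multiplet    — a second tag reaches ``min_count`` and the top/second ratio
  falls below ``dominance_ratio``, or at least two tags reach
  ``min_count * dominance_ratio`` (two genuinely high tags);
* singlet      — otherwise (one clearly dominant tag); the subject is the
  dominant tag's subject.

Three doublet categories are tracked: tag multiplets (above), expression
doublets (imported from an external per-barcode flag file; the detection
algorithm itself is not part of this package), and cross-lineage
"biological" doublets — gated CD4 T cells positive for myeloid markers
(CD33, CD14 by default), flagged per cell or, mirroring the removal of a
whole contaminated cluster, per cluster when more than a cutoff fraction of
the cluster's members are marker-positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagCallParameters:
    min_count: int = 10
    dominance_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.dominance_ratio < 1:
            raise ValueError("dominance_ratio must be >= 1")


def call_tags(
    tags: CountMatrix,
    params: TagCallParameters | None = None,
    tag_to_subject: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every cell as singlet/multiplet/undetermined.

    Returns a frame indexed by barcode with columns tag_call, subject_id
    (dominant tag's subject for singlets, NA otherwise) and top_tag.
    If ``tag_to_subject`` is omitted the tag feature names are used as
    subject identifiers directly.
    """
    params = params or TagCallParameters()
    if tags.shape[1] < 1:
        raise ValueError("tag matrix has no tag features")
    counts = tags.counts.astype(float)
    if counts.sum() == 0:
        warnings.warn("all-zero sample-tag matrix: every cell undetermined", stacklevel=2)
    order = np.argsort(counts, axis=1)
    top_idx = order[:, -1]
    top = counts[np.arange(len(counts)), top_idx]
    second = (
        counts[np.arange(len(counts)), order[:, -2]]
        if counts.shape[1] > 1
        else np.zeros(len(counts))
    )
    mc, dr = params.min_count, params.dominance_ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, top / np.maximum(second, 1e-300), np.inf)
    undetermined = top < mc
    multiplet = (~undetermined) & (
        ((second >= mc) & (ratio < dr)) | (second >= mc * dr)
    )
    singlet = ~(undetermined | multiplet)
    call = np.where(undetermined, "undetermined", np.where(multiplet, "multiplet", "singlet"))
    tag_names = tags.features
    mapping = tag_to_subject or {str(t): str(t) for t in tag_names}
    top_tag = np.asarray([str(tag_names[i]) for i in top_idx], dtype=object)
    subject = pd.array(
        [mapping.get(t, pd.NA) if s else pd.NA for t, s in zip(top_tag, singlet)],
        dtype="string",
    )
    return pd.DataFrame(
        {
            "tag_call": pd.array(call, dtype="string"),
            "subject_id": subject,
            "top_tag": pd.array(top_tag, dtype="string"),
        },
        index=pd.Index(tags.cells, name="barcode"),
    )


DEFAULT_CROSS_LINEAGE_MARKERS = ("CD33", "CD14")


def flag_biological_doublets(
    annotation: pd.DataFrame,
    antibody_positivity: pd.DataFrame,
    markers: tuple[str, ...] = DEFAULT_CROSS_LINEAGE_MARKERS,
    target_type: str = "CD4T",
    level: str = "cluster",
    cluster_fraction_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Flag cross-lineage doublets among cells of ``target_type``.

    ``level='cell'`` flags each target-type cell positive for any
    cross-lineage marker.  ``level='cluster'`` (default) flags every member
    of a cluster in which the marker-positive fraction exceeds
    ``cluster_fraction_cutoff``; it requires a ``cluster_id`` column.
    Returns a copy of the annotation with ``biological_doublet`` updated.
    """
    missing = [m for m in markers if m not in antibody_positivity.columns]
    if missing:
        raise KeyError(
            f"cross-lineage marker(s) {missing} absent; available: "
            f"{sorted(antibody_positivity.columns)}"
        )
    ann = annotation.copy()
    target = ann["major_type"] == target_type
    pos_any = antibody_positivity.loc[ann.index, list(markers)].any(axis=1)
    if level == "cell":
        flag = target & pos_any
    elif level == "cluster":
        if "cluster_id" not in ann.columns:
            raise KeyError("cluster-level flagging needs a cluster_id column")
        flag = pd.Series(False, index=ann.index)
        sub = ann[target & ann["cluster_id"].notna()]
        frac = pos_any[sub.index].groupby(sub["cluster_id"]).mean()
        bad_clusters = frac[frac > cluster_fraction_cutoff].index
        if len(bad_clusters):
            logger.info("flagging clusters %s as biological doublets", list(bad_clusters))
        flag[sub.index[sub["cluster_id"].isin(bad_clusters)]] = True
    else:
        raise ValueError("level must be 'cell' or 'cluster'")
    ann["biological_doublet"] = ann["biological_doublet"] | flag
    return ann


def import_expression_doublets(annotation: pd.DataFrame, flags_csv) -> pd.DataFrame:
    """Merge an external per-barcode expression-doublet flag file.

    The CSV needs columns ``barcode`` and ``expression_doublet`` (truthy).
    """
    ext = pd.read_csv(flags_csv)
    if not {"barcode", "expression_doublet"} <= set(ext.columns):
        raise ValueError("flag file must have barcode and expression_doublet columns")
    flagged = set(ext.loc[ext["expression_doublet"].astype(bool), "barcode"])
    ann = annotation.copy()
    ann["expression_doublet"] = ann["expression_doublet"] | ann.index.isin(flagged)
    return ann


def is_doublet(annotation: pd.DataFrame) -> pd.Series:
    """Union of the three doublet categories (tag call or any flag)."""
    return (
        (annotation["tag_call"] == "multiplet")
        | annotation["tag_multiplet"]
        | annotation["expression_doublet"]
        | annotation["biological_doublet"]
    )
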