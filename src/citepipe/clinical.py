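"""Gensini angiographic burden scoring and CAD severity classification.

Each diseased coronary segment receives a base severity score from its
percent stenosis (0-32 under the conventional breakpoint table), multiplied
by a location weight in [0.5, 5]; the per-segment products sum to the
subject's Gensini score.  Subjects scoring above 30 are classified CAD+,
below 6 CAD-, and anything in between indeterminate (no collateral
adjustment is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix_io import DEFAULT_GENSINI_MAPPING


@dataclass(frozen=True)
class LesionRecord:
    subject_id: str
    segment: str
    percent_stenosis: float
    location_multiplier: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_stenosis <= 100:
            raise ValueError(f"stenosis {self.percent_stenosis} outside [0, 100]")
        if not 0.5 <= self.location_multiplier <= 5:
            raise ValueError(f"multiplier {self.location_multiplier} outside [0.5, 5]")


def _validated_mapping(mapping: dict[int, int] | None) -> list[tuple[float, float]]:
    m = DEFAULT_GENSINI_MAPPING if mapping is None else mapping
    items = sorted((float(k), float(v)) for k, v in m.items())
    scores = [v for _, v in items]
    if scores != sorted(scores) or len(set(scores)) != len(scores):
        raise ValueError("base scores must be strictly increasing with stenosis")
    return items


def segment_score(percent_stenosis: float, mapping: dict[int, int] | None = None) -> float:
    """Base severity score: highest breakpoint whose bound <= stenosis, else 0."""
    if not 0 <= percent_stenosis <= 100:
        raise ValueError(f"stenosis {percent_stenosis} outside [0, 100]")
    score = 0.0
    for bound, base in _validated_mapping(mapping):
        if percent_stenosis >= bound:
            score = base
    return score


def gensini_total(lesions: list[LesionRecord], mapping: dict[int, int] | None = None) -> float:
    """Sum over lesions of segment score times location multiplier."""
    return sum(
        segment_score(les.percent_stenosis, mapping) * les.location_multiplier
        for les in lesions
    )


def classify_cad(score: float) -> str:
    """Gensini > 30 -> CAD+; < 6 -> CAD-; [6, 30] -> indeterminate."""
    if score < 0:
        raise ValueError("Gensini score cannot be negative")
    if score > 30:
        return "CAD+"
    if score < 6:
        return "CAD-"
    return "indeterminate"


def score_subjects(lesions: pd.DataFrame, mapping: dict[int, int] | None = None) -> pd.DataFrame:
    """Score a lesion table (subject_id, segment, stenosis_pct, multiplier).

    Returns one row per subject with gensini_score and cad_class; subjects
    with no lesion rows are not represented (callers treat them as score 0).
    """
    records = [
        LesionRecord(str(r.subject_id), str(r.segment), float(r.stenosis_pct), float(r.multiplier))
        for r in lesions.itertuples(index=False)
    ]
    out = {}
    for rec in records:
        out.setdefault(rec.subject_id, []).append(rec)
    rows = [
        {"subject_id": sid, "gensini_score": (tot := gensini_total(ls, mapping)),
         "cad_class": classify_cad(tot)}
        for sid, ls in sorted(out.items())
    ]
    return pd.DataFrame(rows, columns=["subject_id", "gensini_score", "cad_class"])
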