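"""Antibody (ADT) normalization, background thresholding, and gating.

Antibody UMI counts are centered-log-ratio normalized per cell on the log2
scale.  For each antibody (within a cell-type context) the distribution of
normalized values is modeled as a two-component univariate normal mixture —
a background (non-specific binding) component and a positive component —
fitted by EM.  The positivity threshold is the point between the component
means where the posterior probability of the positive component crosses 0.5
(the Bayes boundary between the two fitted normals).  A negative-reference
rule (mean + k*sd of a known-negative population) is provided as fallback.

Major cell types are gated from thresholded markers with ordered
first-match-wins rules (B cells by CD19, monocytes by CD14/CD16, CD8 T by
CD3/CD8, CD4 T by CD3+CD4+ with lineage-marker negativity).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


def clr_log2(counts: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Per-cell centered log-ratio on the log2 scale.

    value(cell, f) = log2(count + c) - mean_over_features log2(count + c),
    i.e. log2 of (count + c) over the geometric mean of the cell's
    pseudocounted values.  A cell with equal counts maps to all zeros, and
    the transform is invariant to uniform scaling of a cell's pseudocounted
    counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if counts.shape[1] == 0:
        raise ValueError("cannot CLR-normalize a matrix with zero features")
    logx = np.log2(counts.counts + pseudocount)
    values = logx - logx.mean(axis=1, keepdims=True)
    return NormalizedMatrix(counts.cells, counts.features, values, "clr_log2")


# ---------------------------------------------------------------------------
# Two-component normal mixture

@dataclass
class MixtureFit:
    antibody: str
    cell_type_context: str
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    weight_neg: float
    converged: bool
    n_iter: int
    log_likelihood: float
    degenerate: bool = False


class DegenerateDataError(ValueError):
    pass


def _em_once(x, mu1, mu2, sd, max_iter, tol):
    n = len(x)
    w = 0.5
    s1 = s2 = sd
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for stability
        l1 = np.log(w) - 0.5 * np.log(2 * np.pi * s1**2) - (x - mu1) ** 2 / (2 * s1**2)
        l2 = np.log1p(-w) - 0.5 * np.log(2 * np.pi * s2**2) - (x - mu2) ** 2 / (2 * s2**2)
        m = np.maximum(l1, l2)
        lse = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
        ll = lse.sum()
        r1 = np.exp(l1 - lse)
        # M step
        n1 = r1.sum()
        n2 = n - n1
        if n1 < 1e-8 or n2 < 1e-8:
            break
        w = n1 / n
        mu1 = (r1 * x).sum() / n1
        mu2 = ((1 - r1) * x).sum() / n2
        s1 = math.sqrt(max((r1 * (x - mu1) ** 2).sum() / n1, 1e-12))
        s2 = math.sqrt(max(((1 - r1) * (x - mu2) ** 2).sum() / n2, 1e-12))
        if ll_old > -np.inf and abs(ll - ll_old) <= tol * abs(ll_old):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return mu1, s1, mu2, s2, w, converged, it, ll_old


def fit_mixture(
    values,
    antibody: str = "",
    cell_type_context: str = "all",
    max_iter: int = 500,
    tol: float = 1e-6,
    n_init: int = 5,
) -> MixtureFit:
    """Fit a two-component univariate normal mixture by EM.

    Initializations place the component means at spread quantile pairs of
    the data, with both sds at half the pooled sd; the best-likelihood fit is
    returned with components ordered so that mu_neg <= mu_pos.  Requires at
    least 50 finite values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 finite values, got {len(x)}")
    if np.ptp(x) == 0 or x.std() == 0:
        return MixtureFit(antibody, cell_type_context, float(x[0]), 0.0, float(x[0]),
                          0.0, 0.5, False, 0, -np.inf, degenerate=True)
    sd0 = x.std() / 2
    quantile_pairs = [(25, 75), (10, 90), (5, 95), (30, 70), (15, 85)][: max(n_init, 1)]
    best = None
    for qlo, qhi in quantile_pairs:
        mu1, mu2 = np.percentile(x, [qlo, qhi])
        if mu1 == mu2:
            mu2 = mu1 + sd0
        fit = _em_once(x, mu1, mu2, sd0, max_iter, tol)
        if best is None or fit[-1] > best[-1]:
            best = fit
    mu1, s1, mu2, s2, w, converged, it, ll = best
    if mu1 > mu2:  # order components by mean
        mu1, s1, mu2, s2, w = mu2, s2, mu1, s1, 1 - w
    w = min(max(w, 1e-9), 1 - 1e-9)
    return MixtureFit(antibody, cell_type_context, float(mu1), float(s1), float(mu2),
                      float(s2), float(w), bool(converged), int(it), float(ll))


def threshold_from_mixture(fit: MixtureFit) -> float:
    """Posterior-0.5 crossing (Bayes boundary) between the two components.

    Solves w_neg N(x; mu_neg, sd_neg) = w_pos N(x; mu_pos, sd_pos) for x in
    [mu_neg, mu_pos]; falls back to the midpoint of the means (with a
    warning) when no crossing lies in that interval.
    """
    if fit.degenerate:
        raise DegenerateDataError(f"degenerate fit for {fit.antibody}")
    mu1, s1, mu2, s2 = fit.mu_neg, fit.sd_neg, fit.mu_pos, fit.sd_pos
    w1, w2 = fit.weight_neg, 1 - fit.weight_neg
    # log w1 - log s1 - (x-mu1)^2/2s1^2 = log w2 - log s2 - (x-mu2)^2/2s2^2
    a = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = (mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2)
         + math.log(w1 / s1) - math.log(w2 / s2))
    roots: list[float]
    if abs(a) < 1e-12:
        roots = [] if abs(b) < 1e-300 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if mu1 <= r <= mu2]
    if not inside:
        warnings.warn(
            f"no posterior-0.5 crossing between component means for "
            f"{fit.antibody or 'antibody'}; using midpoint", stacklevel=2)
        return (mu1 + mu2) / 2

    def pos_dominant(x: float) -> bool:
        lp1 = math.log(w1 / s1) - (x - mu1) ** 2 / (2 * s1**2)
        lp2 = math.log(w2 / s2) - (x - mu2) ** 2 / (2 * s2**2)
        return lp2 > lp1

    # with two crossings inside, keep the one where the posterior switches
    # from negative- to positive-dominant as x increases
    eps = 1e-6 * max(s1, s2, 1e-6)
    for r in sorted(inside):
        if pos_dominant(r + eps) and not pos_dominant(r - eps):
            return float(r)
    return float(sorted(inside)[0])


def threshold_from_negative_reference(values_in_negative_type, k: float = 3.0) -> float:
    """mean + k*sd of a known-negative population."""
    x = np.asarray(values_in_negative_type, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no negative-reference values")
    if len(x) < 50:
        warnings.warn(
            f"only {len(x)} negative-reference cells; threshold has wide tolerance",
            stacklevel=2)
    return float(x.mean() + k * x.std())


# ---------------------------------------------------------------------------
# Threshold table

def build_threshold_table(
    norm: NormalizedMatrix,
    context: str = "all",
    cells: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_init: int = 5,
    min_separation: float = 2.0,
    min_weight: float = 0.02,
) -> pd.DataFrame:
    """Fit a mixture per antibody and tabulate thresholds.

    Returns rows (antibody, cell_type_context, threshold, method, converged).
    A threshold is only accepted when the fitted components describe two real
    populations: means at least ``min_separation`` pooled sds apart and both
    weights at least ``min_weight`` — otherwise (and for degenerate or
    non-converged fits) the antibody is reported with method 'failed' and a
    NaN threshold.  This is the automated stand-in for inspecting ridgeline
    distributions before trusting a deconvolution.
    """
    df = norm.to_frame()
    if cells is not None:
        df = df.loc[cells]
    rows = []
    for ab in df.columns:
        vals = df[ab].to_numpy()
        try:
            fit = fit_mixture(vals, antibody=str(ab), cell_type_context=context,
                              max_iter=max_iter, tol=tol, n_init=n_init)
        except ValueError:
            rows.append((ab, context, np.nan, "failed", False))
            continue
        pooled_sd = math.sqrt((fit.sd_neg**2 + fit.sd_pos**2) / 2)
        bimodal = (
            pooled_sd > 0
            and (fit.mu_pos - fit.mu_neg) / pooled_sd >= min_separation
            and min_weight <= fit.weight_neg <= 1 - min_weight
        )
        if fit.degenerate or not fit.converged or not bimodal:
            rows.append((ab, context, np.nan, "failed", False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = threshold_from_mixture(fit)
        rows.append((ab, context, thr, "mixture", True))
    return pd.DataFrame(
        rows, columns=["antibody", "cell_type_context", "threshold", "method", "converged"]
    )


def thresholds_as_dict(table: pd.DataFrame, context: str = "all") -> dict[str, float]:
    sub = table[(table["cell_type_context"] == context) & table["threshold"].notna()]
    return dict(zip(sub["antibody"], sub["threshold"]))


def positivity(norm: NormalizedMatrix, thresholds: dict[str, float]) -> pd.DataFrame:
    """Boolean cells x markers frame: value strictly above threshold."""
    df = norm.to_frame()
    missing = set(thresholds) - set(df.columns)
    if missing:
        raise KeyError(f"thresholded markers absent from panel: {sorted(missing)}")
    return pd.DataFrame(
        {m: df[m] > t for m, t in thresholds.items()}, index=df.index
    )


# ---------------------------------------------------------------------------
# Gating

@dataclass(frozen=True)
class GatingRule:
    target: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError(f"rule {self.target}: overlapping marker sets")


#: ordered first-match-wins default gate set
DEFAULT_GATING_RULES: list[GatingRule] = [
    GatingRule("B", positive=("CD19",)),
    GatingRule("Monocyte", positive=("CD14",)),
    GatingRule("Monocyte", positive=("CD16",)),
    GatingRule("CD8T", positive=("CD3", "CD8")),
    GatingRule("CD4T", positive=("CD3", "CD4"),
               negative=("CD8", "CD19", "CD14", "CD16")),
]


def apply_gates(
    norm: NormalizedMatrix,
    thresholds: dict[str, float],
    rules: list[GatingRule] | None = None,
) -> pd.Series:
    """Assign one major type per cell; cells matching no rule become 'Other'."""
    rules = DEFAULT_GATING_RULES if rules is None else rules
    needed = {m for r in rules for m in (*r.positive, *r.negative)}
    missing = needed - set(thresholds)
    if missing:
        raise KeyError(f"no threshold for gating marker(s): {sorted(missing)}")
    pos = positivity(norm, {m: thresholds[m] for m in needed})
    out = pd.Series("Other", index=pos.index, dtype="string", name="major_type")
    unassigned = np.ones(len(pos), dtype=bool)
    for rule in rules:
        match = np.ones(len(pos), dtype=bool)
        for m in rule.positive:
            match &= pos[m].to_numpy()
        for m in rule.negative:
            match &= ~pos[m].to_numpy()
        take = match & unassigned
        out.iloc[np.flatnonzero(take)] = rule.target
        unassigned &= ~take
    return out
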