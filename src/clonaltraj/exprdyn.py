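"""Expression dynamics across passages: presence filtering, one-way
ANOVA differential expression, temporal trend calls and sample
clustering.

A gene is "expressed" when in at least one passage all three replicate
mice exceed the FPKM threshold (default 5, strict).  Differential
expression across the five passages is a fixed-effects one-way ANOVA on
log2(FPKM + 1) (the log stabilizes the variance of FPKM-like data; a
raw-scale mode is kept for sensitivity checks), selected at an
unadjusted P threshold.  Temporal trends are Spearman rank correlations
of per-sample expression against the passage index.  miRNA matrices run
through the same machinery, typically with a lower presence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "AnovaResult",
    "TrendCall",
    "presence_filter",
    "one_way_anova",
    "anova_table",
    "select_degs",
    "cluster_samples",
    "trend_classify",
]

# smallest positive double: stands in for a zero-residual perfect fit so
# that P stays inside (0, 1] while still passing any alpha cut
_P_DEGENERATE = 5e-324


@dataclass(frozen=True)
class AnovaResult:
    feature_id: str
    f_stat: float
    p_value: float
    group_means: tuple[float, ...]
    degenerate: str | None = None  # "zero-residual" | "constant" | None


@dataclass(frozen=True)
class TrendCall:
    feature_id: str
    trend: str  # "up", "down" or "none"
    statistic: float  # Spearman rho vs generation index
    p_value: float

    def __post_init__(self) -> None:
        if self.trend == "up" and not self.statistic > 0:
            raise ValueError("an up trend requires a positive correlation")
        if self.trend == "down" and not self.statistic < 0:
            raise ValueError("a down trend requires a negative correlation")


def presence_filter(e: ExpressionMatrix, threshold: float = 5.0) -> ExpressionMatrix:
    """Keep features expressed above ``threshold`` (strict) in *all*
    replicates of at least one generation."""
    gen_idx = e.sample_sheet.generation_index()
    vals = e.values.to_numpy(dtype=float)
    keep = np.zeros(e.n_features, dtype=bool)
    for g in sorted(set(gen_idx)):
        cols = gen_idx == g
        keep |= (vals[:, cols] > threshold).all(axis=1)
    return ExpressionMatrix(
        e.values.loc[keep], e.sample_sheet, e.feature_kind
    )


def one_way_anova(
    values: np.ndarray,
    groups: np.ndarray,
    feature_id: str = "",
    log_transform: bool = True,
) -> AnovaResult:
    """Fixed-effects one-way ANOVA of one feature across generations.

    F = (SSB / df_b) / (SSW / df_w) with the P value from the upper tail
    of the F distribution; the full 5x3 design has df_b = 4, df_w = 10.
    Computed on log2(value + 1) unless ``log_transform`` is False.

    Degenerate cases: zero within-group variance with unequal means is
    a perfect fit (P reported as the smallest positive float and
    flagged); completely constant input has undefined F (reported as 0
    with P = 1 by convention).
    """
    y = np.asarray(values, dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    groups = np.asarray(groups)
    if np.all(y == y[0]):
        # catch exactly-constant input before sums of squares: the grand
        # mean can differ from the group means by an ulp and fake signal
        levels = np.unique(groups)
        return AnovaResult(
            feature_id, 0.0, 1.0, tuple(float(y[0]) for _ in levels), "constant"
        )
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv} has fewer than two observations")
    grand = y.mean()
    ssb = 0.0
    ssw = 0.0
    means = []
    for lv in levels:
        yy = y[groups == lv]
        m = yy.mean()
        means.append(m)
        ssb += len(yy) * (m - grand) ** 2
        ssw += ((yy - m) ** 2).sum()
    df_b = len(levels) - 1
    df_w = len(y) - len(levels)
    if ssw == 0.0:
        if ssb <= 1e-300:
            return AnovaResult(feature_id, 0.0, 1.0, tuple(means), "constant")
        return AnovaResult(
            feature_id, float("inf"), _P_DEGENERATE, tuple(means), "zero-residual"
        )
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    p = max(p, _P_DEGENERATE)
    return AnovaResult(feature_id, float(f), p, tuple(means))


def anova_table(e: ExpressionMatrix, log_transform: bool = True) -> list[AnovaResult]:
    """Run :func:`one_way_anova` on every feature of a matrix."""
    groups = e.sample_sheet.generation_index()
    vals = e.values.to_numpy(dtype=float)
    return [
        one_way_anova(vals[i], groups, feature_id=f, log_transform=log_transform)
        for i, f in enumerate(e.feature_ids)
    ]


def select_degs(results: list[AnovaResult], alpha: float) -> list[str]:
    """Features with unadjusted P strictly below ``alpha``, sorted by
    ascending P with the feature id as tiebreak."""
    if not results:
        raise ValueError("no ANOVA results to select from")
    hits = [r for r in results if r.p_value < alpha]
    hits.sort(key=lambda r: (r.p_value, r.feature_id))
    return [r.feature_id for r in hits]


def cluster_samples(
    e: ExpressionMatrix, features: list[str], k: int = 2
) -> tuple[dict[str, int], np.ndarray, bool]:
    """Hierarchically cluster samples on a feature subset.

    Average linkage on Euclidean distances between samples, computed on
    log2(value + 1) with each feature row standardized.  Returns the
    sample -> cluster assignment from cutting at ``k`` clusters, the
    scipy linkage matrix, and a degeneracy flag (True when the cut could
    not produce k distinct, non-arbitrary clusters).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if len(features) < 2:
        raise ValueError("need at least two features to cluster on")
    if k > len(e.sample_sheet):
        raise ValueError("k cannot exceed the number of samples")
    sub = e.values.loc[[f for f in e.feature_ids if f in set(features)]]
    X = np.log2(sub.to_numpy(dtype=float) + 1.0)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0  # constant rows carry no signal; leave them centred
    X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    D = pdist(X.T, metric="euclidean")
    degenerate = bool(np.allclose(D, 0))
    Z = hierarchy.linkage(D, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(set(labels)) < k:
        degenerate = True
    # canonical labels: clusters numbered by first sample appearance
    seen: dict[int, int] = {}
    assignment = {}
    for s, lab in zip(e.sample_sheet.sample_ids, labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        assignment[s] = seen[lab]
    return assignment, Z, degenerate


def trend_classify(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    feature_id: str = "",
) -> TrendCall:
    """Spearman-correlation trend of expression against passage index.

    The call is "up"/"down" by the sign of rho when the correlation test
    P < ``alpha``, else "none"; constant input is "none" by definition.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=float)
    if np.all(y == y[0]):
        return TrendCall(feature_id, "none", 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        rho, p = stats.spearmanr(y, g)
    if not np.isfinite(rho):
        return TrendCall(feature_id, "none", 0.0, 1.0)
    p = float(max(p, _P_DEGENERATE)) if np.isfinite(p) else 1.0
    if p < alpha and rho > 0:
        return TrendCall(feature_id, "up", float(rho), p)
    if p < alpha and rho < 0:
        return TrendCall(feature_id, "down", float(rho), p)
    return TrendCall(feature_id, "none", float(rho), p)
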