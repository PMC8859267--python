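"""Shared statistical primitives.

Thin, contract-checked wrappers over scipy where a routine exists, plus the
conventions used throughout the pipeline: two-sided p-values, mid-ranks for
ties, exact small-sample methods where stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: int | None = None
    estimate: float | None = None  # rho / odds ratio / AUC as applicable
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (mid-ranks), two-sided t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman", n=x.size, estimate=float(rho))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p with df = k - 1."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis requires >= 3 total observations")
    if np.ptp(pooled) == 0:
        raise ValueError("kruskal_wallis undefined when all values are identical")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal_wallis", df=len(groups) - 1, n=pooled.size)


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("anova_oneway requires >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("anova undefined: zero within-group variance everywhere")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return TestResult(float(f), float(p), "anova_oneway", df=k - 1, n=n)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U; exact null for m + n <= 12, else normal approximation
    with tie correction. Two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    small = x.size + y.size <= 12
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if small and not ties else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(u), float(min(p, 1.0)), f"wilcoxon_{method}", n=x.size + y.size)


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    p is the sum of hypergeometric probabilities of tables no more likely
    than the observed one. The estimate is the sample odds ratio ad/bc;
    a 0.5 continuity correction is applied (and flagged) only when the
    table contains a zero cell.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("fisher_exact requires non-negative integer counts")
    t = np.round(t).astype(int)
    if t.sum(axis=0).min() <= 0 or t.sum(axis=1).min() <= 0:
        raise ValueError("fisher_exact requires positive margins")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    flags: tuple[str, ...] = ()
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        flags = ("continuity_corrected_or",)
    else:
        odds = a * d / (b * c)
    return TestResult(float(odds), float(min(p, 1.0)), "fisher_exact",
                      n=int(t.sum()), estimate=float(odds), flags=flags)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC via the rank (Mann-Whitney) identity, ties counted 1/2.

    Returns (auc, roc_points) where roc_points is an (k, 2) array of
    (FPR, TPR) pairs over descending score thresholds.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # keep the last index of each distinct threshold
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    return float(auc), np.column_stack([fpr, tpr])
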