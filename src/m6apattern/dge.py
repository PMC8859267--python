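"""Empirical-Bayes moderated two-group differential expression.

Per gene, an ordinary two-group fit gives the residual variance s2_g with
d_g degrees of freedom; hyperparameters (d0, s0^2) are estimated by
method-of-moments on log variances and each gene's variance is squeezed to
stilde2 = (d0*s0^2 + d_g*s2_g) / (d0 + d_g). The moderated t is referred to
a t distribution with d0 + d_g df. Genes with zero residual variance are
excluded from the hyperparameter fit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .io import ExpressionMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class DGEResult:
    table: pd.DataFrame            # index gene: log_fc, t, p, adj_p
    contrast: str
    d0: float                      # prior df (may be inf)
    s0_sq: float                   # prior variance

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df d0 must be >= 0 (possibly inf)")

    def significant(self, alpha_adj: float) -> list[str]:
        return self.table.index[self.table["adj_p"] < alpha_adj].tolist()


def trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (Smyth's scheme)."""
    y = np.asarray(y, float)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on gene variances.

    Returns (d0, s0_sq); d0 = inf when the log-variance spread is no larger
    than expected from sampling noise alone.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * trigamma_inverse(np.array(evar)))
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_t_test(
    m: ExpressionMatrix,
    groups: pd.Series,
    d0_override: float | None = None,
) -> DGEResult:
    """Moderated t-test between the two levels of ``groups``.

    ``groups`` maps sample id to one of exactly two levels; log fold change
    is level2 - level1 in sorted level order. ``d0_override`` forces the
    prior df (0 recovers the ordinary t-test).
    """
    groups = groups.loc[[s for s in m.samples if s in groups.index]]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"moderated_t_test requires exactly 2 group levels, got {levels}")
    idx1 = [s for s in m.samples if groups.get(s) == levels[0]]
    idx2 = [s for s in m.samples if groups.get(s) == levels[1]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")

    X1 = m.values[idx1].to_numpy(float)
    X2 = m.values[idx2].to_numpy(float)
    mu1, mu2 = X1.mean(axis=1), X2.mean(axis=1)
    log_fc = mu2 - mu1
    dg = n1 + n2 - 2
    ss = ((X1 - mu1[:, None]) ** 2).sum(axis=1) + ((X2 - mu2[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.mean(s2[s2 > 0])) if d0 > 0 else 0.0
    else:
        d0, s0_sq = fit_variance_prior(s2, dg)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = float(dg)
    else:
        s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm
        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {"log_fc": log_fc, "t": t, "p": p, "adj_p": bh_adjust(p)}, index=m.genes
    )
    return DGEResult(table=table, contrast=f"{levels[1]}|{levels[0]}", d0=d0, s0_sq=s0_sq)


def phenotype_degs(
    m: ExpressionMatrix,
    labels: pd.Series,
    alpha_adj: float = 0.001,
    combine: str = "intersection",
) -> tuple[list[str], dict[str, DGEResult]]:
    """Signature genes from all pairwise one-vs-one contrasts.

    Returns (signature, per-contrast results). The signature is the
    intersection (default; ``combine='union'`` available) of the BH-significant
    gene sets of the three pairwise contrasts.
    """
    labels = labels.loc[[s for s in m.samples if s in labels.index]]
    levels = sorted(labels.unique())
    if len(levels) != 3:
        raise ValueError(f"phenotype_degs expects 3 clusters, got {levels}")
    for lv in levels:
        if (labels == lv).sum() < 3:
            raise ValueError(f"cluster {lv!r} has < 3 samples")
    results: dict[str, DGEResult] = {}
    sig_sets: list[set[str]] = []
    for a, b in itertools.combinations(levels, 2):
        pair = labels[labels.isin([a, b])]
        sub = ExpressionMatrix(m.values[pair.index.tolist()], m.unit)
        res = moderated_t_test(sub, pair)
        results[f"{a}|{b}"] = res
        sig_sets.append(set(res.significant(alpha_adj)))
    if combine == "intersection":
        sig = set.intersection(*sig_sets)
    elif combine == "union":
        sig = set.union(*sig_sets)
    else:
        raise ValueError("combine must be 'intersection' or 'union'")
    if not sig:
        logger.warning("phenotype_degs: empty signature at alpha_adj=%g", alpha_adj)
    signature = [g for g in m.genes if g in sig]  # preserve matrix order
    return signature, results
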