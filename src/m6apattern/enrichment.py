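"""Single-sample rank-walk enrichment (ssGSEA).

Per sample, genes are ordered by decreasing expression and the enrichment
score is the integrated difference between the weighted in-set ECDF
(weights = ascending mid-rank ^ alpha, so highly expressed genes weigh most)
and the unweighted out-of-set ECDF — the Barbie et al. statistic. Scores
depend on expression only through ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection, read_gmt

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentProfile:
    scores: pd.DataFrame     # gene set x sample
    alpha: float
    normalized: bool

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("non-finite enrichment scores")


def _sample_es(order: np.ndarray, ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Rank-walk ES for one sample.

    order: gene indices by decreasing expression; ranks: ascending mid-ranks
    (highest expression -> largest rank); in_set: boolean per gene.
    """
    mask = in_set[order]
    w = np.where(mask, ranks[order] ** alpha, 0.0)
    denom_in = w.sum()
    n_out = order.size - int(mask.sum())
    cdf_in = np.cumsum(w) / denom_in
    cdf_out = np.cumsum(~mask) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentProfile:
    """Score every gene set in every sample.

    Unmeasured set genes are dropped silently (counts logged); a set with
    fewer than 2 measured genes, or covering all measured genes, is an error.
    Optional min-max normalization rescales each set's scores to [0, 1]
    across samples.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    genes = pd.Index(m.genes)
    X = m.values.to_numpy(float)
    G, S = X.shape

    masks: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        present = genes.isin(members)
        n_in = int(present.sum())
        if n_in < len(members):
            logger.info("ssgsea: set %r uses %d/%d measured genes", name, n_in, len(members))
        if n_in < 2:
            raise ValueError(f"gene set {name!r} has < 2 measured genes after intersection")
        if n_in == G:
            raise ValueError(f"gene set {name!r} covers all measured genes")
        masks[name] = present

    # per-sample descending order (stable on gene index for tie determinism)
    orders = np.argsort(-X, axis=0, kind="stable")
    ranks = rankdata(X, axis=0)  # ascending mid-ranks

    out = np.empty((len(masks), S))
    for j in range(S):
        order_j, ranks_j = orders[:, j], ranks[:, j]
        for i, mask in enumerate(masks.values()):
            out[i, j] = _sample_es(order_j, ranks_j, mask, alpha)

    df = pd.DataFrame(out, index=list(masks), columns=m.samples)
    if normalize:
        rng_ = df.max(axis=1) - df.min(axis=1)
        rng_ = rng_.replace(0, 1.0)
        df = df.sub(df.min(axis=1), axis=0).div(rng_, axis=0)
    return EnrichmentProfile(scores=df, alpha=alpha, normalized=normalize)


def stroma_immune_panels(path: str | None = None) -> GeneSetCollection:
    """Bundled panel registry: TME cell-type markers, stromal activity
    pathways (EMT1-3, Pan-F-TBRS, angiogenesis) and immune panels."""
    if path is not None:
        return read_gmt(path)
    ref = resources.files("m6apattern.data").joinpath("panels.gmt")
    if not ref.is_file():
        raise FileNotFoundError("packaged panels.gmt resource missing")
    with resources.as_file(ref) as p:
        return read_gmt(p)
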