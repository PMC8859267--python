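"""Subsampled consensus clustering with CDF/delta-area model selection.

For each candidate k, samples are repeatedly subsampled and clustered
(k-means on z-scored feature rows by default); the consensus matrix entry
for a sample pair is the fraction of co-subsampled runs in which the pair
co-clustered. k is chosen by the delta-area rule on the consensus-CDF area
(k=2 area taken absolutely, larger k scored by relative area increase), and
final labels come from average-linkage hierarchical clustering of
1 - consensus.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io import ExpressionMatrix, zscore_genes


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]          # k -> (n, n) matrix in [0, 1]
    chosen_k: int
    labels: pd.Series                         # sample id -> cluster name
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, mat in self.consensus.items():
            if not np.allclose(mat, mat.T):
                raise ValueError(f"consensus matrix for k={k} not symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"consensus matrix for k={k} lacks unit diagonal")
            if mat.min() < -1e-12 or mat.max() > 1 + 1e-12:
                raise ValueError(f"consensus entries for k={k} outside [0, 1]")
        if self.chosen_k not in self.consensus:
            raise ValueError("chosen k outside searched range")
        if self.labels.isna().any():
            raise ValueError("labels must cover all samples")

    def cluster_sizes(self) -> dict[str, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _cdf_area(mat: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries."""
    vals = np.sort(mat[np.triu_indices_from(mat, k=1)])
    n = vals.size
    if n == 0:
        return 0.0
    area = 0.0
    prev = vals[0]
    for i in range(1, n):
        area += (vals[i] - prev) * (i / n)
        prev = vals[i]
    area += (1.0 - prev) * 1.0
    return float(area)


def consensus_cluster(
    m: ExpressionMatrix,
    features: Sequence[str],
    k_range: Sequence[int] = range(2, 7),
    reps: int = 250,
    frac: float = 0.8,
    seed: int = 0,
    n_init: int = 1,
    elbow_frac: float = 0.5,
) -> ConsensusResult:
    """Consensus-cluster samples on the given feature genes.

    Raises if features are missing from the matrix, if ``reps`` < 10, if
    ``frac`` is outside (0.5, 1], or if max(k_range) exceeds n_samples - 1.
    """
    features = list(features)
    missing = [g for g in features if g not in m.values.index]
    if missing:
        raise ValueError(f"feature genes absent from matrix: {missing}")
    k_range = sorted(set(int(k) for k in k_range))
    n = m.shape[1]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range {k_range} outside [2, {n - 1}]")
    if reps < 10:
        raise ValueError("reps must be >= 10")
    if not (0.5 < frac <= 1.0):
        raise ValueError("frac must lie in (0.5, 1]")

    sub = m.subset_genes(features)
    if sub.unit != "ZSCORE":
        sub = zscore_genes(sub)
    X = sub.values.to_numpy(float).T  # samples x features

    n_sub = int(np.floor(frac * n))
    rng = np.random.default_rng(seed)
    subsamples = [rng.choice(n, size=n_sub, replace=False) for _ in range(reps)]
    km_seeds = rng.integers(0, 2**31 - 1, size=(reps, len(k_range)))

    consensus: dict[int, np.ndarray] = {}
    co_sampled = np.zeros((n, n))
    for idx in subsamples:
        ind = np.zeros(n)
        ind[idx] = 1.0
        co_sampled += np.outer(ind, ind)

    for kj, k in enumerate(k_range):
        co_clustered = np.zeros((n, n))
        for rep, idx in enumerate(subsamples):
            km = KMeans(n_clusters=k, n_init=n_init, random_state=int(km_seeds[rep, kj]))
            lab = km.fit_predict(X[idx])
            onehot = np.zeros((n, k))
            onehot[idx, lab] = 1.0
            co_clustered += onehot @ onehot.T
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(mat, 1.0)
        consensus[k] = np.clip((mat + mat.T) / 2, 0.0, 1.0)

    areas = {k: _cdf_area(consensus[k]) for k in k_range}
    deltas: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[k_range[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    # elbow reading of the delta-area curve: keep every k whose delta-area
    # is still a substantial fraction of the largest one (splitting a real
    # cluster collapses the delta), then take the largest such k
    max_delta = max(deltas.values())
    chosen_k = max(k for k, d in deltas.items() if d >= elbow_frac * max_delta)

    dist = 1.0 - consensus[chosen_k]
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(link, t=chosen_k, criterion="maxclust")
    labels = pd.Series([f"cluster_{c}" for c in raw], index=m.samples, name="cluster")

    return ConsensusResult(
        consensus=consensus,
        chosen_k=chosen_k,
        labels=labels,
        cdf_areas=areas,
        delta_areas=deltas,
        settings={"reps": reps, "frac": frac, "seed": seed, "k_range": k_range,
                  "base": "kmeans", "n_init": n_init, "elbow_frac": elbow_frac},
    )


def assign_pattern_names(result: ConsensusResult, m: ExpressionMatrix) -> ConsensusResult:
    """Rename clusters deterministically by descending mean z-scored feature
    expression: A, B, C for k=3 (cluster_1..k with a warning otherwise).

    Ties are broken by cluster size (descending), then by the
    lexicographically smallest member sample id.
    """
    import logging

    sub = m if m.unit == "ZSCORE" else zscore_genes(m)
    mean_z = sub.values.mean(axis=0)  # per sample

    stats = []
    for name, members in result.labels.groupby(result.labels).groups.items():
        members = list(members)
        stats.append((name, float(mean_z.loc[members].mean()), len(members), min(members)))
    # descending mean, descending size, ascending smallest id
    stats.sort(key=lambda t: (-round(t[1], 12), -t[2], t[3]))

    if result.chosen_k == 3:
        new_names = list(string.ascii_uppercase[: len(stats)])
    else:
        logging.getLogger(__name__).warning(
            "assign_pattern_names: chosen k = %d != 3; keeping numeric names", result.chosen_k
        )
        new_names = [f"cluster_{i + 1}" for i in range(len(stats))]
    mapping = {old: new for (old, _, _, _), new in zip(stats, new_names)}
    relabeled = result.labels.map(mapping)
    return ConsensusResult(
        consensus=result.consensus,
        chosen_k=result.chosen_k,
        labels=relabeled,
        cdf_areas=result.cdf_areas,
        delta_areas=result.delta_areas,
        settings={**result.settings, "named": True},
    )
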