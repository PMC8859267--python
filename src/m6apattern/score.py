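"""m6Ascore signature: prognostic gene filter, PCA model, scoring,
stratification, and downstream association analyses.

The score of a sample is sigma * (projection onto loading 1 + projection
onto loading 2) of its z-scored expression over the prognostic gene panel
(equivalently, the gene-wise sum of the first two component contributions).
The orientation sign sigma is fixed so the score correlates non-negatively
with the risk-direction-weighted mean z-expression of the panel (per-gene
univariate Cox coefficient signs; plain mean when unknown), making the
direction reproducible across runs and aligning "high score" with "high
hazard".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import EnrichmentProfile
from .io import ClinicalTable, ExpressionMatrix
from .stats import TestResult, kruskal_wallis, roc_auc, spearman, wilcoxon_rank_sum
from .survival import CutpointResult, cox_fit, maxstat_cutpoint

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class M6AScoreModel:
    genes: list[str]
    gene_p: dict[str, float]           # univariate Cox Wald p per gene
    means: np.ndarray                  # per-gene normalization constants
    sds: np.ndarray
    loading1: np.ndarray               # unit-norm gene loadings, PC1
    loading2: np.ndarray               # unit-norm gene loadings, PC2
    sign: int                          # orientation sigma in {+1, -1}
    explained_variance: tuple[float, float]

    def __post_init__(self) -> None:
        for v in (self.loading1, self.loading2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError("loadings must be unit-norm")
        if abs(float(self.loading1 @ self.loading2)) > 1e-8:
            raise ValueError("loadings must be orthogonal")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if len(self.genes) != self.means.size or len(self.genes) != self.sds.size:
            raise ValueError("normalization constants missing for some genes")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "genes": self.genes,
            "gene_p": self.gene_p,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loading1": self.loading1.tolist(),
            "loading2": self.loading2.tolist(),
            "sign": self.sign,
            "explained_variance": list(self.explained_variance),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "M6AScoreModel":
        d = json.loads(Path(path).read_text())
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')}")
        return cls(
            genes=d["genes"],
            gene_p={k: float(v) for k, v in d["gene_p"].items()},
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loading1=np.array(d["loading1"]),
            loading2=np.array(d["loading2"]),
            sign=int(d["sign"]),
            explained_variance=tuple(d["explained_variance"]),
        )


@dataclass
class ScoreTable:
    scores: pd.Series                       # sample -> m6Ascore
    groups: pd.Series | None = None         # sample -> "high"/"low"
    threshold: float | None = None
    cutpoint: CutpointResult | None = None

    def __post_init__(self) -> None:
        if self.groups is not None:
            if not self.groups.index.equals(self.scores.index):
                raise ValueError("groups must partition exactly the scored samples")
            if not set(self.groups.unique()) <= {"high", "low"}:
                raise ValueError("groups must be 'high'/'low'")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"m6ascore": self.scores})
        if self.groups is not None:
            df["group"] = self.groups
            df["threshold"] = self.threshold
        return df


def filter_prognostic_genes(
    m: ExpressionMatrix,
    clinical: ClinicalTable,
    signature_genes: list[str],
    p_thresh: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Keep signature genes whose z-scored expression has univariate Cox
    Wald p < p_thresh.

    Returns (genes, stats) where stats holds the per-gene Wald p and Cox
    coefficient (the coefficient sign is the gene's risk direction, reused
    to orient the score). Errors if < 2 genes survive."""
    sub = m.subset_genes(signature_genes)
    time, event, samples = clinical.survival(
        [s for s in sub.samples if s in clinical.table.index]
    )
    if len(samples) < 3 or event.sum() == 0:
        raise ValueError("insufficient survival information for prognostic filter")
    X = sub.values[samples].to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    rows: dict[str, tuple[float, float]] = {}
    for i, g in enumerate(sub.genes):
        if sd[i, 0] == 0:
            continue
        z = (X[i] - mu[i, 0]) / sd[i, 0]
        fit = cox_fit(time, event, z)
        rows[g] = (float(fit.p[0]), float(fit.beta[0]))
    stats = pd.DataFrame.from_dict(rows, orient="index", columns=["p", "coef"])
    kept = [g for g in sub.genes if g in stats.index and stats.loc[g, "p"] < p_thresh]
    logger.info("prognostic filter: kept %d/%d genes at p<%g", len(kept), len(signature_genes), p_thresh)
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} prognostic gene(s) at p < {p_thresh}; PCA impossible")
    return kept, stats.loc[kept]


def fit_score_model(
    m: ExpressionMatrix,
    gene_stats: pd.DataFrame | None = None,
) -> M6AScoreModel:
    """PCA (via SVD of the z-scored gene x sample matrix) retaining
    components 1 and 2.

    ``gene_stats`` (optional; the prognostic filter output with a ``coef``
    column) supplies per-gene risk directions used by the orientation rule;
    without it the unweighted mean z-expression is the reference."""
    genes = m.genes
    if len(genes) < 2 or m.shape[1] < 3:
        raise ValueError("fit_score_model needs >= 2 genes and >= 3 samples")
    X = m.values.to_numpy(float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = [g for g, s in zip(genes, sds) if s == 0]
        raise ValueError(f"zero-variance gene(s): {bad}")
    Z = (X - means[:, None]) / sds[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if S.size < 2 or S[1] <= S[0] * 1e-12:
        raise ValueError("matrix rank < 2; two components unavailable")

    # deterministic per-component sign convention before orientation:
    # largest-|loading| entry positive
    for c in (0, 1):
        pivot = np.argmax(np.abs(U[:, c]))
        if U[pivot, c] < 0:
            U[:, c] = -U[:, c]
            Vt[c] = -Vt[c]

    proj = (U[:, 0] + U[:, 1]) @ Z          # per-sample raw score
    # orientation reference: risk-direction-weighted mean z-expression
    # (falls back to the plain mean when no risk directions are known)
    if gene_stats is not None and "coef" in gene_stats.columns:
        signs = np.sign(gene_stats.reindex(genes)["coef"].fillna(0.0).to_numpy())
        mean_z = signs @ Z / len(genes)
    else:
        mean_z = Z.mean(axis=0)
    sd_p, sd_m = proj.std(), mean_z.std()
    if sd_p > 0 and sd_m > 0:
        corr = float(np.corrcoef(proj, mean_z)[0, 1])
    else:
        corr = 0.0
    sign = 1 if corr >= 0 else -1

    ev = (S**2) / np.sum(S**2)
    gene_p: dict[str, float] = {}
    if gene_stats is not None and "p" in gene_stats.columns:
        gene_p = {g: float(gene_stats.loc[g, "p"]) for g in genes if g in gene_stats.index}
    return M6AScoreModel(
        genes=genes,
        gene_p=gene_p,
        means=means,
        sds=sds,
        loading1=U[:, 0].copy(),
        loading2=U[:, 1].copy(),
        sign=sign,
        explained_variance=(float(ev[0]), float(ev[1])),
    )


def compute_m6ascore(model: M6AScoreModel, m: ExpressionMatrix) -> ScoreTable:
    missing = [g for g in model.genes if g not in m.values.index]
    if missing:
        raise ValueError(f"matrix lacks model gene(s): {missing}")
    X = m.values.loc[model.genes].to_numpy(float)
    Z = (X - model.means[:, None]) / model.sds[:, None]
    raw = (model.loading1 + model.loading2) @ Z
    scores = pd.Series(model.sign * raw, index=m.samples, name="m6ascore")
    return ScoreTable(scores=scores)


def stratify_by_score(
    table: ScoreTable,
    clinical: ClinicalTable,
    min_frac: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ScoreTable:
    """Split samples into high/low m6Ascore groups at the maxstat threshold."""
    shared = [s for s in table.scores.index if s in clinical.table.index]
    time, event, samples = clinical.survival(shared)
    cut = maxstat_cutpoint(
        time, event, table.scores.loc[samples].to_numpy(),
        min_frac=min_frac, n_permutations=n_permutations, seed=seed,
    )
    groups = pd.Series(
        np.where(table.scores > cut.threshold, "high", "low"),
        index=table.scores.index, name="group",
    )
    logger.info("stratify_by_score: %d high / %d low at threshold %.4g",
                (groups == "high").sum(), (groups == "low").sum(), cut.threshold)
    return ScoreTable(scores=table.scores, groups=groups,
                      threshold=cut.threshold, cutpoint=cut)


@dataclass
class AssociationReport:
    cluster_kw: TestResult | None = None
    gene_cluster_kw: TestResult | None = None
    subtype_tests: dict[str, TestResult] = field(default_factory=dict)
    response_test: TestResult | None = None
    response_auc: float | None = None
    enrichment_corr: pd.DataFrame | None = None
    medians: dict[str, dict[str, float]] = field(default_factory=dict)


def score_associations(
    table: ScoreTable,
    clusters: pd.Series | None = None,
    gene_clusters: pd.Series | None = None,
    subtype: pd.Series | None = None,
    response: pd.Series | None = None,
    enrichment: EnrichmentProfile | None = None,
) -> AssociationReport:
    """Score-vs-annotation association battery (KW / Wilcoxon / Spearman / ROC)."""
    scores = table.scores
    report = AssociationReport()

    def _grouped(lab: pd.Series) -> tuple[list[np.ndarray], list[str]]:
        shared = lab.index.intersection(scores.index)
        if shared.empty:
            raise ValueError("no sample overlap between scores and labels")
        lab = lab.loc[shared]
        names = sorted(lab.unique())
        return [scores.loc[lab.index[lab == g]].to_numpy() for g in names], names

    if clusters is not None:
        vals, names = _grouped(clusters)
        report.cluster_kw = kruskal_wallis(vals)
        report.medians["cluster"] = {n: float(np.median(v)) for n, v in zip(names, vals)}
    if gene_clusters is not None:
        vals, names = _grouped(gene_clusters)
        report.gene_cluster_kw = kruskal_wallis(vals)
        report.medians["gene_cluster"] = {n: float(np.median(v)) for n, v in zip(names, vals)}
    if subtype is not None:
        vals, names = _grouped(subtype)
        if len(vals) == 2:
            report.subtype_tests["subtype"] = wilcoxon_rank_sum(vals[0], vals[1])
        else:
            report.subtype_tests["subtype"] = kruskal_wallis(vals)
    if response is not None:
        shared = response.index.intersection(scores.index)
        if shared.empty:
            raise ValueError("no sample overlap between scores and response")
        r = response.loc[shared].astype(int)
        s = scores.loc[shared]
        report.response_test = wilcoxon_rank_sum(s[r == 1].to_numpy(), s[r == 0].to_numpy())
        auc, _ = roc_auc(s.to_numpy(), r.to_numpy())
        report.response_auc = float(auc)
    if enrichment is not None:
        shared = enrichment.scores.columns.intersection(scores.index)
        if shared.empty:
            raise ValueError("no sample overlap between scores and enrichment profile")
        rows = []
        for name in enrichment.scores.index:
            es = enrichment.scores.loc[name, shared].to_numpy()
            if np.ptp(es) == 0:
                continue
            res = spearman(scores.loc[shared].to_numpy(), es)
            rows.append((name, res.estimate, res.p_value))
        report.enrichment_corr = pd.DataFrame(
            rows, columns=["set", "rho", "p"]
        ).set_index("set")
    return report
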