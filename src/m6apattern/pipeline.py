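"""End-to-end workflow: preprocess -> regulator patterns -> enrichment ->
DEG signature -> gene clusters -> prognostic filter -> m6Ascore -> survival,
association and mutation summaries, with a single results bundle.

One config seed fans out to per-stage seeds through a stable stage-name
hash, so every stage can be re-run independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .consensus import ConsensusResult, assign_pattern_names, consensus_cluster
from .dge import DGEResult, phenotype_degs
from .enrichment import EnrichmentProfile, ssgsea_scores
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .mutation import (
    CnvMatrix,
    MutationTable,
    cnv_frequency,
    mutation_frequency,
    pairwise_cooccurrence,
    tmb,
    tmb_score_association,
)
from .score import (
    AssociationReport,
    M6AScoreModel,
    ScoreTable,
    compute_m6ascore,
    filter_prognostic_genes,
    fit_score_model,
    score_associations,
    stratify_by_score,
)
from .survival import cox_fit, kaplan_meier, logrank_test

logger = logging.getLogger(__name__)

PIPELINE_VERSION = "0.1.0"


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the config seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    expression_path: str
    clinical_path: str
    out_dir: str
    mutation_path: str | None = None
    cnv_path: str | None = None
    gmt_path: str | None = None
    regulator_catalog_path: str | None = None
    expression_unit: str = "FPKM"
    k_range: tuple[int, int] = (2, 6)
    reps: int = 250
    frac: float = 0.8
    alpha: float = 0.25
    alpha_adj: float = 0.001
    p_thresh: float = 0.05
    min_frac: float = 0.1
    maxstat_permutations: int = 200
    seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def validate(self, n_samples: int | None = None) -> None:
        if self.reps < 10:
            raise ValueError("reps must be >= 10")
        if not (0.5 < self.frac <= 1.0):
            raise ValueError("frac must lie in (0.5, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 < self.alpha_adj <= 1):
            raise ValueError("alpha_adj must lie in (0, 1]")
        if not (0 < self.p_thresh <= 1):
            raise ValueError("p_thresh must lie in (0, 1]")
        if not (0 < self.min_frac < 0.5):
            raise ValueError("min_frac must lie in (0, 0.5)")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid k_range {self.k_range}")
        if n_samples is not None and hi > n_samples - 1:
            raise ValueError(f"k_range max {hi} exceeds n_samples - 1 = {n_samples - 1}")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    clusters: ConsensusResult
    enrichment: EnrichmentProfile | None
    dge_results: dict[str, DGEResult]
    signature: list[str]
    gene_clusters: ConsensusResult
    score_model: M6AScoreModel
    score_table: ScoreTable
    survival_tables: dict[str, pd.DataFrame]
    score_group_cox: pd.DataFrame
    associations: AssociationReport
    mutation_summary: dict = field(default_factory=dict)
    contingency: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = _time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
            logger.info("stage=%s elapsed=%.2fs", name, _time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def preprocess_expression(
    m: ExpressionMatrix, clinical: ClinicalTable
) -> ExpressionMatrix:
    """FPKM -> TPM -> log2, then ComBat on the clinical cohort column."""
    if m.unit == "FPKM":
        m = io_mod.fpkm_to_tpm(m)
    if m.unit == "TPM":
        m = io_mod.log2_transform(m)
    if m.unit != "LOG2":
        raise ValueError(f"cannot preprocess matrix in unit {m.unit}")
    if "cohort" in clinical.table.columns:
        batches = clinical.table.loc[m.samples, "cohort"]
        if batches.nunique() >= 2 and batches.value_counts().min() >= 2:
            m = io_mod.combat_correct(m, batches)
    return m


def run_pipeline_data(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig,
    mutations: MutationTable | None = None,
    cnv: CnvMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    regulators: list[str] | None = None,
) -> ResultsBundle:
    """Run every analysis stage on in-memory inputs."""
    config.validate(n_samples=expression.shape[1])
    seed = config.seed
    k_range = range(config.k_range[0], config.k_range[1] + 1)

    if regulators is None:
        catalog = io_mod.load_regulator_catalog(config.regulator_catalog_path)
        regulators = catalog.genes
    present = [g for g in regulators if g in expression.values.index]
    if len(present) < 2:
        raise StageError("preprocess", ValueError("fewer than 2 regulator genes measured"))

    m = _stage("preprocess")(preprocess_expression)(expression, clinical)

    clusters = _stage("regulator_consensus")(consensus_cluster)(
        m, present, k_range=k_range, reps=config.reps, frac=config.frac,
        seed=stage_seed(seed, "regulator_consensus"),
    )
    clusters = _stage("pattern_naming")(assign_pattern_names)(
        clusters, m.subset_genes(present)
    )

    enrichment = None
    if gene_sets is not None and len(gene_sets):
        enrichment = _stage("enrichment")(ssgsea_scores)(m, gene_sets, alpha=config.alpha)

    signature, dge_results = _stage("deg_signature")(phenotype_degs)(
        m, clusters.labels, alpha_adj=config.alpha_adj
    )
    if len(signature) < 2:
        raise StageError("deg_signature", ValueError(
            f"signature has {len(signature)} gene(s); cannot continue"))

    gene_clusters = _stage("gene_consensus")(consensus_cluster)(
        m, signature, k_range=k_range, reps=config.reps, frac=config.frac,
        seed=stage_seed(seed, "gene_consensus"),
    )
    gene_clusters = _stage("gene_cluster_naming")(assign_pattern_names)(
        gene_clusters, m.subset_genes(signature)
    )

    prognostic, gene_stats = _stage("prognostic_filter")(filter_prognostic_genes)(
        m, clinical, signature, p_thresh=config.p_thresh
    )
    model = _stage("score_model")(fit_score_model)(m.subset_genes(prognostic), gene_stats)
    score_table = _stage("scoring")(compute_m6ascore)(model, m)
    score_table = _stage("stratify")(stratify_by_score)(
        score_table, clinical,
        min_frac=config.min_frac,
        n_permutations=config.maxstat_permutations,
        seed=stage_seed(seed, "stratify"),
    )

    survival_tables = _stage("survival")(
        _survival_tables
    )(clinical, clusters.labels, gene_clusters.labels, score_table)

    time, event, samples = clinical.survival(score_table.scores.index)
    grp = (score_table.groups.loc[samples] == "high").astype(float)
    cox = cox_fit(time, event, pd.DataFrame({"high_score": grp.to_numpy()}))
    score_group_cox = cox.summary()

    tab = clinical.table
    associations = _stage("associations")(score_associations)(
        score_table,
        clusters=clusters.labels,
        gene_clusters=gene_clusters.labels,
        subtype=tab["subtype"] if "subtype" in tab.columns else None,
        response=tab["response"] if "response" in tab.columns else None,
        enrichment=enrichment,
    )

    mutation_summary: dict = {}
    if mutations is not None:
        per_gene, any_freq = mutation_frequency(mutations, regulators, len(mutations.samples))
        mutation_summary["per_gene_pct"] = per_gene
        mutation_summary["any_regulator_pct"] = any_freq
        mutation_summary["cooccurrence"] = pairwise_cooccurrence(mutations, regulators)
        counts = tmb(mutations)
        mutation_summary["tmb"] = counts
        try:
            mutation_summary["tmb_association"] = tmb_score_association(
                counts, score_table.scores, score_table.groups
            )
        except ValueError:
            pass
    if cnv is not None:
        mutation_summary["cnv_frequency"] = cnv_frequency(cnv)

    contingency = _stage("contingency")(_contingency)(
        clusters.labels, gene_clusters.labels, score_table, clinical
    )

    provenance = {
        "config_hash": config.content_hash(),
        "seed": seed,
        "version": PIPELINE_VERSION,
        "n_samples": expression.shape[1],
        "n_genes": expression.shape[0],
        "stage_seeds": {s: stage_seed(seed, s)
                        for s in ("regulator_consensus", "gene_consensus", "stratify")},
    }
    return ResultsBundle(
        clusters=clusters,
        enrichment=enrichment,
        dge_results=dge_results,
        signature=signature,
        gene_clusters=gene_clusters,
        score_model=model,
        score_table=score_table,
        survival_tables=survival_tables,
        score_group_cox=score_group_cox,
        associations=associations,
        mutation_summary=mutation_summary,
        contingency=contingency,
        provenance=provenance,
    )


def _survival_tables(
    clinical: ClinicalTable,
    clusters: pd.Series,
    gene_clusters: pd.Series,
    score_table: ScoreTable,
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for name, labels in (
        ("m6a_cluster", clusters),
        ("gene_cluster", gene_clusters),
        ("score_group", score_table.groups),
    ):
        time, event, samples = clinical.survival(labels.index)
        lab = labels.loc[samples]
        rows = []
        for g in sorted(lab.unique()):
            mask = (lab == g).to_numpy()
            fit = kaplan_meier(time[mask], event[mask])
            median = np.nan
            below = fit.survival <= 0.5
            if below.any():
                median = float(fit.times[np.argmax(below)])
            rows.append({"group": g, "n": int(mask.sum()), "events": int(event[mask].sum()),
                         "median_survival_months": median})
        df = pd.DataFrame(rows).set_index("group")
        levels = sorted(lab.unique())
        if len(levels) == 2:
            res = logrank_test(time, event, lab.to_numpy())
            df.attrs["logrank_p"] = res.p_value
        elif len(levels) > 2:
            ps = {}
            for i, a in enumerate(levels):
                for b in levels[i + 1:]:
                    mask = lab.isin([a, b]).to_numpy()
                    res = logrank_test(time[mask], event[mask], lab[mask].to_numpy())
                    ps[f"{a}|{b}"] = res.p_value
            df.attrs["pairwise_logrank_p"] = ps
        out[name] = df
    return out


def _contingency(
    clusters: pd.Series,
    gene_clusters: pd.Series,
    score_table: ScoreTable,
    clinical: ClinicalTable,
) -> pd.DataFrame:
    """Long-format cluster -> gene cluster -> score group -> outcome counts
    (tabular alluvial analog)."""
    idx = clusters.index
    df = pd.DataFrame({
        "m6a_cluster": clusters,
        "gene_cluster": gene_clusters.loc[idx],
        "score_group": score_table.groups.loc[idx],
    })
    outcome = clinical.table.reindex(idx)["event"].map({0: "alive/censored", 1: "dead"})
    df["outcome"] = outcome.fillna("unknown")
    counts = (
        df.groupby(["m6a_cluster", "gene_cluster", "score_group", "outcome"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return counts


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> dict[str, str]:
    """Persist every stage output as plain text under ``out_dir``; returns a
    filename -> sha256 manifest (also written as manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.clusters.labels.rename("cluster").to_csv(out / "m6a_clusters.tsv", sep="\t")
    bundle.gene_clusters.labels.rename("gene_cluster").to_csv(out / "gene_clusters.tsv", sep="\t")
    (out / "signature_genes.txt").write_text("\n".join(bundle.signature) + "\n")
    for contrast, res in bundle.dge_results.items():
        safe = contrast.replace("|", "_vs_")
        res.table.to_csv(out / f"dge_{safe}.tsv", sep="\t")
    if bundle.enrichment is not None:
        bundle.enrichment.scores.to_csv(out / "enrichment_scores.tsv", sep="\t")
    bundle.score_model.to_json(out / "score_model.json")
    bundle.score_table.to_frame().to_csv(out / "m6ascore.tsv", sep="\t")
    for name, df in bundle.survival_tables.items():
        extra = {k: v for k, v in df.attrs.items()}
        df.to_csv(out / f"survival_{name}.tsv", sep="\t")
        if extra:
            (out / f"survival_{name}_tests.json").write_text(json.dumps(extra, indent=1, sort_keys=True))
    bundle.score_group_cox.to_csv(out / "score_group_cox.tsv", sep="\t")
    if bundle.contingency is not None:
        bundle.contingency.to_csv(out / "contingency.tsv", sep="\t", index=False)
    ms = bundle.mutation_summary
    if "per_gene_pct" in ms:
        ms["per_gene_pct"].to_csv(out / "mutation_frequency.tsv", sep="\t")
        (out / "mutation_any_regulator.json").write_text(
            json.dumps({"any_regulator_pct": ms["any_regulator_pct"]}))
    if "cooccurrence" in ms:
        ms["cooccurrence"].to_csv(out / "mutation_cooccurrence.tsv", sep="\t", index=False)
    if "tmb" in ms:
        ms["tmb"].to_csv(out / "tmb.tsv", sep="\t")
    if "cnv_frequency" in ms:
        ms["cnv_frequency"].to_csv(out / "cnv_frequency.tsv", sep="\t")
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=1, sort_keys=True))

    manifest = {}
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_full_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Load inputs from config paths, run every stage, persist the bundle."""
    config.validate()
    expression = io_mod.read_expression(config.expression_path, unit=config.expression_unit)
    clinical = io_mod.read_clinical(config.clinical_path)
    mutations = (MutationTable.from_tsv(config.mutation_path, samples=expression.samples)
                 if config.mutation_path else None)
    cnv = CnvMatrix.from_tsv(config.cnv_path) if config.cnv_path else None
    gene_sets = io_mod.read_gmt(config.gmt_path) if config.gmt_path else None
    bundle = run_pipeline_data(
        expression, clinical, config, mutations=mutations, cnv=cnv, gene_sets=gene_sets
    )
    write_bundle(bundle, config.out_dir)
    return bundle
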