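"""Synthetic cohort generator with planted ground truth.

Generates an FPKM expression matrix (lognormal background, cluster-specific
regulator/signature shifts, additive cohort batch effects), proportional-
hazards survival tied to a latent per-sample score, regulator mutations and
CNV states, a binary immunotherapy response, and TME panels with planted
per-cluster enrichment — everything the analysis pipeline consumes, plus a
truth record sufficient to recompute every planted quantity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    load_regulator_catalog,
    write_clinical,
    write_expression,
    write_gmt,
)
from .mutation import CnvMatrix, MutationTable


@dataclass
class GeneratorConfig:
    n_samples: int = 440
    cluster_sizes: tuple[int, ...] = (133, 172, 135)
    n_cohorts: int = 3
    batch_sd: float = 0.4
    n_genes: int = 2000
    n_de: int = 983                  # signature genes with three pattern means
    n_prognostic: int = 100          # DE genes additionally tied to the latent score
    regulator_effect: float = 1.5    # z-units between pattern means
    de_effect: float = 1.0
    prognostic_effect: float = 0.5   # loading of latent score on prognostic genes
    noise_sd: float = 1.0
    n_panels: int = 5
    panel_size: int = 15
    panel_effect: float = 1.5
    score_separation: float = 1.0    # latent-score cluster-mean spacing
    baseline_hazard: float = 0.02    # events per month
    log_hr: float = float(np.log(2.0))  # per latent-score SD
    censor_horizon: float = 100.0    # months
    regulator_any_mutation_rate: float = 0.162
    tmb_lambda: float = 40.0
    response_slope: float = -1.0     # low score -> responder
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_samples:
            raise ValueError(
                f"cluster sizes {self.cluster_sizes} do not sum to n_samples={self.n_samples}"
            )
        if self.regulator_effect <= 0 and self.regulator_effect != 0:
            raise ValueError("regulator_effect must be >= 0")
        if not (0 <= self.regulator_any_mutation_rate <= 1):
            raise ValueError("mutation rate must lie in [0, 1]")
        n_special = 21 + self.n_de + self.n_panels * self.panel_size
        if self.n_genes < n_special:
            raise ValueError(f"n_genes={self.n_genes} < required {n_special}")


@dataclass
class SyntheticTruth:
    cluster: pd.Series                  # sample -> planted pattern name (A/B/C/...)
    latent_score: pd.Series
    responder_prob: pd.Series
    de_genes: list[str]
    prognostic_genes: list[str]
    panel_cluster: dict[str, str]       # set name -> enriched pattern
    config: GeneratorConfig
    seed: int


@dataclass
class SyntheticBundle:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    cnv: CnvMatrix
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def _cluster_names(k: int) -> list[str]:
    import string

    return list(string.ascii_uppercase[:k])


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Draw one synthetic cohort. ``seed`` overrides ``config.seed``."""
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.cluster_sizes)
    names = _cluster_names(k)
    n = cfg.n_samples

    samples = [f"S{i + 1:04d}" for i in range(n)]
    cluster_idx = np.repeat(np.arange(k), cfg.cluster_sizes)
    cluster = pd.Series([names[c] for c in cluster_idx], index=samples, name="cluster")
    cohort = rng.integers(0, cfg.n_cohorts, size=n)

    regulators = load_regulator_catalog().genes
    de_genes = [f"DEG_{i + 1:04d}" for i in range(cfg.n_de)]
    panel_genes = [
        f"MARK{p + 1}_{g + 1:02d}" for p in range(cfg.n_panels) for g in range(cfg.panel_size)
    ]
    n_bg = cfg.n_genes - len(regulators) - cfg.n_de - len(panel_genes)
    bg_genes = [f"BG_{i + 1:04d}" for i in range(n_bg)]
    genes = regulators + de_genes + panel_genes + bg_genes
    G = len(genes)

    # latent score: cluster-ordered means (first pattern highest) + unit noise
    cluster_means = cfg.score_separation * (np.arange(k)[::-1] - (k - 1) / 2.0)
    latent = cluster_means[cluster_idx] + rng.normal(0, 1, n)
    latent_z = (latent - latent.mean()) / latent.std(ddof=1)

    # log2-scale expression
    base = rng.normal(4.0, 1.0, G)
    L = base[:, None] + rng.normal(0, cfg.noise_sd, (G, n))

    # per-gene pattern profile: random permutation of equispaced levels, so
    # the k planted pattern centroids are near-equidistant in feature space
    levels = np.linspace(-1.0, 1.0, k)
    reg_profiles = np.stack([rng.permutation(levels) for _ in regulators])
    for i in range(len(regulators)):
        L[i] += cfg.regulator_effect * reg_profiles[i, cluster_idx]

    # three distinct per-cluster means for every signature gene; prognostic
    # genes get the pattern aligned with the latent-score cluster ordering
    # (risk genes monotone in risk) plus a direct latent loading
    de_levels = np.linspace(-1.0, 1.0, k)
    de_offset = len(regulators)
    prognostic_genes = de_genes[: cfg.n_prognostic]
    aligned = de_levels[::-1].copy()  # first pattern (highest latent) highest
    for i in range(cfg.n_de):
        perm = aligned if i < cfg.n_prognostic else rng.permutation(de_levels)
        L[de_offset + i] += cfg.de_effect * perm[cluster_idx]
    for i in range(cfg.n_prognostic):
        L[de_offset + i] += cfg.prognostic_effect * latent_z

    # TME panels: one designated pattern is up-shifted per panel
    panel_cluster: dict[str, str] = {}
    sets: dict[str, list[str]] = {}
    p_offset = de_offset + cfg.n_de
    for p in range(cfg.n_panels):
        target = p % k
        name = f"panel_{p + 1}"
        members = panel_genes[p * cfg.panel_size : (p + 1) * cfg.panel_size]
        sets[name] = members
        panel_cluster[name] = names[target]
        rows = slice(p_offset + p * cfg.panel_size, p_offset + (p + 1) * cfg.panel_size)
        L[rows] += cfg.panel_effect * (cluster_idx == target)

    # cohort batch shifts (cohort 0 is the reference)
    batch_shift = rng.normal(0, cfg.batch_sd, (G, cfg.n_cohorts))
    batch_shift[:, 0] = 0.0
    L += batch_shift[:, cohort]

    fpkm = np.power(2.0, L)
    expression = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples), "FPKM")

    # survival: exponential PH on the standardized latent score
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hr * latent_z)
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0, cfg.censor_horizon, n)
    event = (t_event <= censor).astype(int)
    time = np.maximum(np.minimum(t_event, censor), 0.01)

    # immunotherapy response: logistic in the latent score
    prob = 1.0 / (1.0 + np.exp(-cfg.response_slope * latent_z))
    responder = rng.binomial(1, prob)
    response_cat = np.where(
        responder == 1,
        rng.choice(["CR", "PR"], size=n),
        rng.choice(["SD", "PD"], size=n),
    )

    clinical = ClinicalTable(pd.DataFrame(
        {
            "time_months": np.round(time, 3),
            "event": event,
            "age": rng.integers(30, 85, n),
            "gender": rng.choice(["female", "male"], size=n),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n),
            "cohort": [f"cohort_{c + 1}" for c in cohort],
            "subtype": rng.choice(["HPV+", "HPV-"], size=n),
            "response": responder,
            "response_cat": response_cat,
        },
        index=pd.Index(samples, name="sample"),
    ))

    # mutations: regulator rate tuned for the target any-regulator frequency
    per_gene_rate = 1.0 - (1.0 - cfg.regulator_any_mutation_rate) ** (1.0 / len(regulators))
    records = []
    reg_mut = rng.random((len(regulators), n)) < per_gene_rate
    for i, g in enumerate(regulators):
        for j in np.flatnonzero(reg_mut[i]):
            records.append((samples[j], g, "Missense_Mutation", "SNP"))
    burden = rng.poisson(cfg.tmb_lambda, n)
    for j in range(n):
        hit = rng.choice(len(bg_genes), size=burden[j], replace=True)
        for h in hit:
            records.append((samples[j], bg_genes[h], "Missense_Mutation", "SNP"))
        for h in rng.choice(len(bg_genes), size=rng.poisson(3.0), replace=True):
            records.append((samples[j], bg_genes[h], "Silent", "SNP"))
    mutations = MutationTable(
        pd.DataFrame(records, columns=[
            "Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification", "Variant_Type",
        ]),
        samples=samples,
    )

    # CNV: amplification-biased regulator states
    states = rng.choice([-1, 0, 1], size=(len(regulators), n), p=[0.05, 0.85, 0.10])
    cnv = CnvMatrix(pd.DataFrame(states, index=regulators, columns=samples))

    truth = SyntheticTruth(
        cluster=cluster,
        latent_score=pd.Series(latent, index=samples, name="latent_score"),
        responder_prob=pd.Series(prob, index=samples, name="responder_prob"),
        de_genes=de_genes,
        prognostic_genes=prognostic_genes,
        panel_cluster=panel_cluster,
        config=cfg,
        seed=cfg.seed,
    )
    return SyntheticBundle(
        expression=expression,
        clinical=clinical,
        mutations=mutations,
        cnv=cnv,
        gene_sets=GeneSetCollection(sets),
        truth=truth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(bundle: SyntheticBundle, directory: str | Path) -> dict[str, str]:
    """Write the bundle as plain-text files; returns {filename: sha256}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression, directory / "expression.tsv")
    write_clinical(bundle.clinical, directory / "clinical.tsv")
    bundle.mutations.to_tsv(directory / "mutations.tsv")
    bundle.cnv.to_tsv(directory / "cnv.tsv")
    write_gmt(bundle.gene_sets, directory / "panels.gmt")
    truth = bundle.truth
    (directory / "truth.json").write_text(json.dumps(
        {
            "seed": truth.seed,
            "config": dataclasses.asdict(truth.config),
            "cluster": truth.cluster.to_dict(),
            "latent_score": {s: float(v) for s, v in truth.latent_score.items()},
            "responder_prob": {s: float(v) for s, v in truth.responder_prob.items()},
            "de_genes": truth.de_genes,
            "prognostic_genes": truth.prognostic_genes,
            "panel_cluster": truth.panel_cluster,
        },
        indent=1, sort_keys=True,
    ))
    manifest = {
        f.name: _sha256(f)
        for f in sorted(directory.iterdir())
        if f.name != "manifest.json" and f.is_file()
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def verify_fixture(directory: str | Path) -> bool:
    """Check every manifest entry against the file on disk."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return all(_sha256(directory / name) == digest for name, digest in manifest.items())
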