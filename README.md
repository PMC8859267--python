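# m6apattern

Analysis toolkit for discovering N6-methyladenosine (m6A) regulator-defined
modification patterns in bulk expression cohorts, deriving a phenotype gene
signature, scoring samples (m6Ascore), and quantifying associations with the
tumor microenvironment, survival, somatic mutations, and immunotherapy
response.

The pipeline, end to end:

1. **Preprocessing** — FPKM → TPM → log2, ComBat (parametric empirical-Bayes)
   batch correction across cohorts.
2. **Modification patterns** — subsampled consensus clustering of the
   21-gene regulator panel, with CDF/delta-area selection of the cluster
   number and deterministic A/B/C pattern naming.
3. **TME / pathway activity** — single-sample rank-walk enrichment (ssGSEA)
   against bundled immune-cell and stromal-pathway panels or any GMT.
4. **Phenotype signature** — empirical-Bayes moderated-t differential
   expression across all pairwise pattern contrasts; the signature is the
   three-way overlap at BH-adjusted p < 0.001.
5. **Gene clusters** — consensus clustering of samples on the signature.
6. **m6Ascore** — univariate Cox filter of the signature, PCA of the
   retained panel; score = oriented sum of the first two component
   projections. High/low groups via the maximally selected log-rank
   cutpoint (permutation-corrected p).
7. **Outcome analyses** — Kaplan–Meier/log-rank, Cox PH (Efron ties),
   Kruskal–Wallis/Wilcoxon/Spearman/ROC association battery, mutation
   frequency + Fisher co-occurrence, TMB, CNV gain/loss summaries, and a
   tabular cluster → gene-cluster → score-group → outcome contingency
   export.

A fully planted synthetic-cohort generator (`m6apattern.simulate`) provides
ground truth for every stage and backs the test suite.

## CLI

```sh
# generate a synthetic fixture directory (expression/clinical/MAF/CNV/GMT + truth)
m6apattern simulate --seed 7 --out fixtures/

# consensus clustering of a feature panel
m6apattern cluster --expr expr.tsv --features regulators.txt --k 2..6 \
    --reps 250 --seed 7 --out clusters.tsv

# ssGSEA enrichment scores
m6apattern enrich --expr expr.tsv --gmt sets.gmt --alpha 0.25 --out es.tsv

# score new samples with a serialized model and stratify
m6apattern score --expr expr.tsv --clinical clinical.tsv \
    --model score_model.json --seed 7 --out scores.tsv

# full pipeline from a YAML config
m6apattern run --config pipeline.yaml
```

A pipeline config lists input paths plus stage parameters
(`k_range`, `reps`, `frac`, `alpha`, `alpha_adj`, `p_thresh`, `min_frac`,
`maxstat_permutations`, `seed`, `out_dir`); see
`m6apattern.pipeline.PipelineConfig`. One config seed fans out to
deterministic per-stage seeds, and the results directory carries a
sha256 manifest — identical config + seed reproduces byte-identical output.

## Library layout

| module | contents |
| --- | --- |
| `m6apattern.io` | expression/clinical/GMT types + readers, TPM/log2/z-score, ComBat, regulator catalog |
| `m6apattern.stats` | BH, Spearman, Kruskal–Wallis, ANOVA, Wilcoxon, Fisher exact, ROC/AUC |
| `m6apattern.consensus` | consensus clustering + pattern naming |
| `m6apattern.enrichment` | ssGSEA + bundled TME/stromal panels |
| `m6apattern.dge` | moderated-t DGE and the overlap signature |
| `m6apattern.survival` | Kaplan–Meier, log-rank, Cox PH, maxstat cutpoint |
| `m6apattern.score` | prognostic filter, score model, scoring, stratification, associations |
| `m6apattern.mutation` | MAF-like records, mutation/CNV/TMB/co-occurrence summaries |
| `m6apattern.simulate` | synthetic cohort generator with planted truth |
| `m6apattern.pipeline` | orchestration, results bundle, manifest |

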