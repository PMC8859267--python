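"""Somatic mutation and copy-number summaries.

Consumes MAF-like TSV records (Tumor_Sample_Barcode, Hugo_Symbol,
Variant_Classification, Variant_Type) and a pre-discretized gene x sample
copy-number state matrix in {-1, 0, +1}.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, fisher_exact, spearman, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

NONSILENT = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "Splice_Site",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Translation_Start_Site",
    "Nonstop_Mutation",
})

MAF_VOCABULARY = NONSILENT | frozenset({
    "Silent", "3'UTR", "5'UTR", "Intron", "IGR", "RNA", "3'Flank", "5'Flank",
})

MAF_COLUMNS = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification", "Variant_Type"]


@dataclass
class MutationTable:
    records: pd.DataFrame
    samples: list[str] = field(default_factory=list)   # full sample universe
    nonsilent: frozenset = NONSILENT

    def __post_init__(self) -> None:
        missing = [c for c in MAF_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation records missing column(s): {missing}")
        bad = set(self.records["Variant_Classification"]) - MAF_VOCABULARY
        if bad:
            raise ValueError(f"unknown Variant_Classification value(s): {sorted(bad)}")
        if not self.samples:
            self.samples = sorted(self.records["Tumor_Sample_Barcode"].unique())

    @classmethod
    def from_tsv(cls, path: str | Path, samples: list[str] | None = None) -> "MutationTable":
        return cls(pd.read_csv(path, sep="\t"), samples=samples or [])

    def to_tsv(self, path: str | Path) -> None:
        self.records[MAF_COLUMNS].to_csv(path, sep="\t", index=False)

    def binary_matrix(self) -> pd.DataFrame:
        """Gene x sample 0/1 matrix of nonsilent mutation status."""
        ns = self.records[self.records["Variant_Classification"].isin(self.nonsilent)]
        if ns.empty:
            return pd.DataFrame(0, index=[], columns=self.samples, dtype=int)
        ct = pd.crosstab(ns["Hugo_Symbol"], ns["Tumor_Sample_Barcode"])
        ct = (ct > 0).astype(int)
        return ct.reindex(columns=self.samples, fill_value=0).sort_index()


@dataclass
class CnvMatrix:
    states: pd.DataFrame   # gene x sample in {-1, 0, +1}

    def __post_init__(self) -> None:
        vals = set(np.unique(self.states.to_numpy()))
        if not vals <= {-1, 0, 1}:
            raise ValueError(f"CNV states must be -1/0/+1, found {sorted(vals)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CnvMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0).astype(int))

    def to_tsv(self, path: str | Path) -> None:
        df = self.states.copy()
        df.index.name = df.index.name or "gene"
        df.to_csv(path, sep="\t")


def mutation_frequency(
    mut: MutationTable, genes: list[str], n_total: int
) -> tuple[pd.Series, float]:
    """Per-gene and any-gene nonsilent mutation frequencies (percent,
    2 decimals). Unknown genes get frequency 0 with a warning."""
    mat = mut.binary_matrix()
    n_mutated_samples = len(set(mut.records.loc[
        mut.records["Variant_Classification"].isin(mut.nonsilent), "Tumor_Sample_Barcode"
    ]) & set(mut.samples)) if len(mut.records) else 0
    if n_total < n_mutated_samples:
        raise ValueError("n_total smaller than the number of mutated samples")
    per_gene = {}
    any_mask = pd.Series(False, index=mat.columns) if len(mat) else pd.Series(dtype=bool)
    for g in genes:
        if g in mat.index:
            per_gene[g] = round(float(mat.loc[g].sum()) / n_total * 100, 2)
            any_mask = any_mask | (mat.loc[g] > 0)
        else:
            logger.warning("mutation_frequency: gene %r absent from records", g)
            per_gene[g] = 0.0
    any_freq = round(float(any_mask.sum()) / n_total * 100, 2) if len(any_mask) else 0.0
    return pd.Series(per_gene, name="mutation_pct"), any_freq


def cooccurrence_test(mut: MutationTable, gene_a: str, gene_b: str) -> tuple[TestResult, str]:
    """Fisher test of mutation co-occurrence between two genes.

    Direction is 'co-occurrence' when the sample odds ratio exceeds 1,
    'exclusivity' otherwise. Genes never mutated are untestable.
    """
    mat = mut.binary_matrix()
    for g in (gene_a, gene_b):
        if g not in mat.index or mat.loc[g].sum() == 0:
            raise ValueError(f"gene {g!r} never mutated; co-occurrence untestable")
    a = mat.loc[gene_a].to_numpy(bool)
    b = mat.loc[gene_b].to_numpy(bool)
    table = [
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ]
    res = fisher_exact(table)
    direction = "co-occurrence" if res.estimate > 1 else "exclusivity"
    return res, direction


def pairwise_cooccurrence(mut: MutationTable, genes: list[str]) -> pd.DataFrame:
    """All-pairs co-occurrence tests with BH adjustment across testable pairs."""
    mat = mut.binary_matrix()
    testable = [g for g in genes if g in mat.index and mat.loc[g].sum() > 0]
    skipped = sorted(set(genes) - set(testable))
    if skipped:
        logger.info("pairwise_cooccurrence: %d untestable gene(s): %s", len(skipped), skipped[:10])
    rows = []
    for ga, gb in itertools.combinations(testable, 2):
        res, direction = cooccurrence_test(mut, ga, gb)
        rows.append((ga, gb, res.estimate, res.p_value, direction))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "odds_ratio", "p", "direction"])
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
    else:
        df["adj_p"] = []
    return df


def tmb(mut: MutationTable) -> pd.Series:
    """Per-sample nonsilent mutation count (no per-megabase scaling)."""
    ns = mut.records[mut.records["Variant_Classification"].isin(mut.nonsilent)]
    counts = ns.groupby("Tumor_Sample_Barcode").size()
    return counts.reindex(mut.samples, fill_value=0).rename("tmb")


def tmb_score_association(
    tmb_counts: pd.Series, scores: pd.Series, groups: pd.Series | None = None
) -> dict[str, TestResult]:
    shared = tmb_counts.index.intersection(scores.index)
    if len(shared) < 3:
        raise ValueError("tmb_score_association requires >= 3 shared samples")
    out = {"spearman": spearman(tmb_counts.loc[shared].to_numpy(),
                                scores.loc[shared].to_numpy())}
    if groups is not None:
        g = groups.loc[groups.index.intersection(shared)]
        hi = tmb_counts.loc[g.index[g == "high"]].to_numpy()
        lo = tmb_counts.loc[g.index[g == "low"]].to_numpy()
        if hi.size and lo.size:
            out["wilcoxon_high_vs_low"] = wilcoxon_rank_sum(hi, lo)
    return out


def cnv_frequency(cnv: CnvMatrix) -> pd.DataFrame:
    """Per-gene gain (+1) and loss (-1) frequencies."""
    arr = cnv.states.to_numpy()
    n = arr.shape[1]
    return pd.DataFrame(
        {
            "gain_freq": (arr == 1).sum(axis=1) / n,
            "loss_freq": (arr == -1).sum(axis=1) / n,
        },
        index=cnv.states.index,
    )


def waterfall_matrix(mut: MutationTable, top_n: int = 20) -> pd.DataFrame:
    """Top-N most-mutated genes x samples binary matrix (tabular oncoprint)."""
    mat = mut.binary_matrix()
    if mat.empty:
        return mat
    top = mat.sum(axis=1).sort_values(ascending=False).index[:top_n]
    return mat.loc[top]
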