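"""Domain types, file readers/writers, and expression preprocessing.

Expression matrices are gene x sample pandas DataFrames carrying a unit tag
(FPKM, TPM, LOG2, ZSCORE); unit transitions happen only through the declared
operations below (``fpkm_to_tpm``, ``log2_transform``, ``zscore_genes``).
Batch correction follows the parametric empirical-Bayes location/scale model
of Johnson et al. (ComBat), without covariate preservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = ("FPKM", "TPM", "LOG2", "ZSCORE")

ROLES = ("writer", "eraser", "reader")


class ExpressionError(ValueError):
    """Raised for malformed expression input."""


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with a unit tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples. All entries must be finite.
    unit : str
        One of ``FPKM``, ``TPM``, ``LOG2``, ``ZSCORE``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ExpressionError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ExpressionError(f"duplicate gene identifiers: {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ExpressionError(f"duplicate sample identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ExpressionError(
                f"non-numeric value at gene {idx[r]!r}, sample {cols[c]!r}"
            )
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionError(
                f"non-finite value at gene {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ExpressionError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.unit)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation with survival columns.

    ``table`` is indexed by sample id and carries at least ``time_months``
    and ``event`` wherever survival is available; additional covariates
    (age, gender, stage, cohort, response, ...) are passed through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = sorted(self.table.index[self.table.index.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample identifiers in clinical table: {dups}")
        if "event" in self.table.columns:
            ev = self.table["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValueError("event column must be coded 0/1")
        if "time_months" in self.table.columns:
            t = self.table["time_months"].dropna()
            if (t <= 0).any():
                raise ValueError("time_months must be > 0 where present")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def survival(self, samples: Iterable[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (time, event, sample ids) for samples with complete survival."""
        tab = self.table if samples is None else self.table.loc[list(samples)]
        tab = tab.dropna(subset=["time_months", "event"])
        return (
            tab["time_months"].to_numpy(float),
            tab["event"].to_numpy(int),
            list(tab.index),
        )


@dataclass
class RegulatorCatalog:
    """Mapping from regulator gene symbol to functional role."""

    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g: r for g, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"invalid regulator roles: {bad}; allowed {ROLES}")

    @property
    def genes(self) -> list[str]:
        return list(self.roles)

    def __len__(self) -> int:
        return len(self.roles)

    def by_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        # set names are dict keys, hence unique by construction

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "tsv", unit: str = "FPKM") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    TSV dialect: tab-separated, first column gene id, header row sample ids,
    UTF-8, '.' decimal. GCT: the two header lines ("#1.2" and dimensions)
    are skipped and the Description column is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ExpressionError(f"{path}: not a GCT file (first line {version!r})")
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=2)
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'gct'")
    non_numeric = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna()].tolist()
        raise ExpressionError(
            f"{path}: non-numeric cell(s) in sample column {col!r}, gene row(s) {bad_rows}"
        )
    m = ExpressionMatrix(df, unit)
    logger.info("read_expression: %s -> %d genes x %d samples [%s]", path, *m.shape, unit)
    return m


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    df = c.table.copy()
    df.index.name = df.index.name or "sample"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} in {path}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def load_regulator_catalog(path: str | Path | None = None, apply_aliases: bool = True) -> RegulatorCatalog:
    """Load a regulator catalog (TSV: gene<TAB>role).

    The packaged default lists the 21-gene writer/eraser/reader panel; the
    METTL13 entry is mapped to METTL3 by default (METTL13 has no documented
    methyltransferase role on mRNA and downstream analyses use METTL3).
    Pass ``apply_aliases=False`` to keep the list verbatim.
    """
    if path is None:
        ref = resources.files("m6apattern.data").joinpath("regulators.tsv")
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    roles: dict[str, str] = {}
    for gene, role in zip(df["gene"], df["role"]):
        if apply_aliases and gene == "METTL13":
            logger.warning("regulator catalog: mapping listed METTL13 -> METTL3")
            gene = "METTL3"
        if gene in roles:
            raise ValueError(f"duplicate regulator {gene!r} in catalog")
        roles[gene] = role
    return RegulatorCatalog(roles)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Column-normalize FPKM to TPM: TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6."""
    if m.unit != "FPKM":
        raise ExpressionError(f"fpkm_to_tpm requires FPKM input, got {m.unit}")
    arr = m.values.to_numpy(float)
    if (arr < 0).any():
        raise ExpressionError("negative FPKM values")
    colsum = arr.sum(axis=0)
    zero = np.flatnonzero(colsum <= 0)
    if zero.size:
        raise ExpressionError(f"all-zero expression column(s): {[m.samples[i] for i in zero]}")
    out = arr / colsum * 1e6
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), "TPM")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    arr = m.values.to_numpy(float)
    if (arr < 0).any():
        raise ExpressionError("log2_transform requires non-negative input")
    out = np.log2(arr + pseudocount)
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), "LOG2")


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row across samples (sample SD, ddof=1).

    Genes with zero variance are dropped with a warning.
    """
    if m.shape[1] < 2:
        raise ExpressionError("zscore_genes requires >= 2 samples")
    arr = m.values.to_numpy(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = [g for g, k in zip(m.genes, keep) if not k]
    if dropped:
        logger.warning("zscore_genes: dropping %d constant gene(s): %s", len(dropped), dropped[:10])
    z = (arr[keep] - mu[keep]) / sd[keep]
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.values.index[keep], columns=m.values.columns), "ZSCORE"
    )


def combat_correct(m: ExpressionMatrix, batch: Iterable[str]) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch correction (ComBat model).

    Per gene: standardize against the sample-size-weighted grand mean and
    pooled variance, estimate per-batch location/scale effects, shrink them
    toward the across-gene prior, then remove and rescale. Grand-mean
    structure is preserved. No biological covariates are modelled.
    """
    batch = np.asarray(list(batch))
    if batch.shape[0] != m.shape[1]:
        raise ValueError("batch label vector length must equal number of samples")
    levels, codes = np.unique(batch, return_inverse=True)
    if len(levels) == 1:
        return ExpressionMatrix(m.values.copy(), m.unit)
    counts = np.bincount(codes)
    if (counts < 2).any():
        bad = levels[counts < 2].tolist()
        raise ValueError(f"batch(es) with fewer than 2 samples: {bad}")

    X = m.values.to_numpy(float)
    G, N = X.shape
    B = len(levels)

    batch_means = np.stack([X[:, codes == b].mean(axis=1) for b in range(B)], axis=1)  # G x B
    grand_mean = batch_means @ (counts / N)
    fitted = batch_means[:, codes]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    ok = var_pooled > 0
    sd = np.sqrt(np.where(ok, var_pooled, 1.0))

    Z = (X - grand_mean[:, None]) / sd[:, None]

    gamma_hat = np.stack([Z[:, codes == b].mean(axis=1) for b in range(B)], axis=1)
    delta_hat = np.stack([Z[:, codes == b].var(axis=1, ddof=1) for b in range(B)], axis=1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)

    def _aprior(d):
        mu, s2 = d.mean(), d.var(ddof=1)
        return (2 * s2 + mu**2) / s2

    def _bprior(d):
        mu, s2 = d.mean(), d.var(ddof=1)
        return (mu * s2 + mu**3) / s2

    Xc = np.empty_like(X)
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(B):
        n_b = counts[b]
        a, bp = _aprior(delta_hat[:, b]), _bprior(delta_hat[:, b])
        g_old = gamma_hat[:, b].copy()
        d_old = delta_hat[:, b].copy()
        Zb = Z[:, codes == b]
        for _ in range(100):
            g_new = (tau2[b] * n_b * gamma_hat[:, b] + d_old * gamma_bar[b]) / (
                tau2[b] * n_b + d_old
            )
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + bp) / (n_b / 2 + a - 1)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
            )
            g_old, d_old = g_new, d_new
            if change < 1e-4:
                break
        gamma_star[:, b], delta_star[:, b] = g_old, d_old

    for b in range(B):
        mask = codes == b
        Xc[:, mask] = (Z[:, mask] - gamma_star[:, b][:, None]) / np.sqrt(
            delta_star[:, b][:, None]
        ) * sd[:, None] + grand_mean[:, None]
    Xc[~ok] = X[~ok]  # constant genes untouched

    return ExpressionMatrix(pd.DataFrame(Xc, index=m.values.index, columns=m.values.columns), m.unit)
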