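"""RPKM quantification and differential-expression calling.

Expression is quantified as RPKM = 1e9 * count / (library_size *
exon_length).  Differential expression between two conditions uses the
conditional test on pooled per-gene counts: condition-B count versus the
library-size-ratio expectation, two-sided (minimum-likelihood), BH-corrected.
With ``dispersion=0`` this is the exact binomial conditional test (the
Poisson-count case); with ``dispersion>0`` the binomial is replaced by a
moment-matched beta-binomial so the test stays calibrated for
negative-binomially overdispersed counts.  A gene is DE when |fold| exceeds
``fold_threshold``, FDR is below ``fdr_threshold``, and the larger group
mean RPKM exceeds ``min_rpkm``.  For real datasets a precomputed DE table
can be supplied verbatim instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "rpkm",
    "call_de",
    "de_from_table",
    "read_counts_tsv",
]

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_FDR_THRESHOLD = 0.001
DEFAULT_MIN_RPKM = 1.0


def rpkm(count: float, exon_length: int, library_size: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length <= 0:
        raise ValueError("exon_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e9 * count / (library_size * exon_length)


@dataclass
class ExpressionTable:
    """Gene-level integer counts with exon lengths and library sizes."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    exon_lengths: pd.Series  # bp per gene
    library_sizes: pd.Series | None = None  # per sample; default column sums

    def __post_init__(self) -> None:
        cnt = self.counts.to_numpy()
        if np.any(cnt < 0) or not np.issubdtype(cnt.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if not self.exon_lengths.index.equals(self.counts.index):
            self.exon_lengths = self.exon_lengths.reindex(self.counts.index)
        if self.exon_lengths.isna().any() or (self.exon_lengths < 1).any():
            raise ValueError("every gene needs exon_length >= 1")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def rpkm_matrix(self) -> pd.DataFrame:
        lib = self.library_sizes.reindex(self.counts.columns).to_numpy(float)
        lengths = self.exon_lengths.to_numpy(float)
        return pd.DataFrame(
            1e9 * self.counts.to_numpy(float) / (lib[None, :] * lengths[:, None]),
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.exon_lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> ExpressionTable:
    """Read a counts TSV with columns: gene_id, length, one per sample."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValueError(f"{path}: counts table needs a 'length' column")
    lengths = df["length"]
    counts = df.drop(columns="length").astype(np.int64)
    return ExpressionTable(counts=counts, exon_lengths=lengths)


def _two_sided_tail_p(
    y: np.ndarray, n: np.ndarray, p0: float, dispersion: float
) -> np.ndarray:
    """Minimum-likelihood two-sided p for y successes of n at null rate p0.

    dispersion 0 -> binomial; >0 -> beta-binomial with intra-class
    correlation rho ~= 2*phi*p0*(1-p0) (moment-matched to the variance of a
    count contrast between two NB samples with gene-wise dispersion phi).
    """
    out = np.ones(len(y))
    if dispersion > 0:
        rho = min(2.0 * dispersion * p0 * (1 - p0), 0.999)
        conc = 1.0 / rho - 1.0
        a_par, b_par = p0 * conc, (1 - p0) * conc
    for i, (yi, ni) in enumerate(zip(y, n)):
        if ni == 0:
            continue
        k = np.arange(ni + 1)
        if dispersion > 0:
            pmf = stats.betabinom.pmf(k, ni, a_par, b_par)
        else:
            pmf = stats.binom.pmf(k, ni, p0)
        # sum of all outcomes no more likely than the observed one
        out[i] = min(1.0, pmf[pmf <= pmf[yi] * (1 + 1e-7)].sum())
    return out


def call_de(
    counts_a: np.ndarray | pd.DataFrame,
    counts_b: np.ndarray | pd.DataFrame,
    exon_lengths: pd.Series | np.ndarray,
    gene_ids: Sequence[str] | None = None,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_rpkm: float = DEFAULT_MIN_RPKM,
    dispersion: float = 0.0,
) -> pd.DataFrame:
    """Differential-expression calls between conditions A (control) and B.

    ``counts_a``/``counts_b`` are genes x replicates (1-D accepted for one
    replicate); replicates are pooled within condition.  Returns a per-gene
    table with log2_fold, p, fdr, rpkm_a, rpkm_b, and is_de.  All-zero genes
    get p = 1 and are excluded from the BH denominator.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=np.int64).T).T
    b = np.atleast_2d(np.asarray(counts_b, dtype=np.int64).T).T
    if a.shape[0] != b.shape[0]:
        raise ValueError("conditions cover different numbers of genes")
    if isinstance(counts_a, pd.DataFrame) and gene_ids is None:
        gene_ids = list(counts_a.index)
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(a.shape[0])]
    lengths = np.asarray(exon_lengths, dtype=float)
    tot_a = a.sum(axis=1)
    tot_b = b.sum(axis=1)
    lib_a = int(tot_a.sum())
    lib_b = int(tot_b.sum())
    if lib_a == 0 or lib_b == 0:
        raise ValueError("a condition has zero total counts")
    p0 = lib_b / (lib_a + lib_b)
    pooled = tot_a + tot_b
    nonzero = pooled > 0
    pvals = np.ones(len(gene_ids))
    pvals[nonzero] = _two_sided_tail_p(
        tot_b[nonzero], pooled[nonzero], p0, dispersion
    )
    # moderated CPM fold change (0.5-count prior per library)
    cpm_a = (tot_a + 0.5) / (lib_a + 1) * 1e6
    cpm_b = (tot_b + 0.5) / (lib_b + 1) * 1e6
    log2_fold = np.log2(cpm_b / cpm_a)
    fdr = np.ones(len(gene_ids))
    if nonzero.any():
        fdr[nonzero] = multipletests(pvals[nonzero], method="fdr_bh")[1]
    rpkm_a = 1e9 * tot_a / a.shape[1] / (lib_a / a.shape[1]) / lengths
    rpkm_b = 1e9 * tot_b / b.shape[1] / (lib_b / b.shape[1]) / lengths
    is_de = (
        (np.abs(log2_fold) > np.log2(fold_threshold))
        & (fdr < fdr_threshold)
        & (np.maximum(rpkm_a, rpkm_b) > min_rpkm)
    )
    return pd.DataFrame(
        {
            "log2_fold": log2_fold,
            "p": pvals,
            "fdr": fdr,
            "rpkm_a": rpkm_a,
            "rpkm_b": rpkm_b,
            "is_de": is_de,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def de_from_table(
    table: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_rpkm: float | None = None,
) -> pd.DataFrame:
    """Apply the DE thresholds to a precomputed table.

    Requires columns gene_id (or index), log2fc (or log2_fold), fdr;
    optional rpkm column enables the expression floor.
    """
    df = table.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    if "log2fc" in df.columns:
        df = df.rename(columns={"log2fc": "log2_fold"})
    for col in ("log2_fold", "fdr"):
        if col not in df.columns:
            raise ValueError(f"DE table missing required column {col!r}")
    is_de = (np.abs(df["log2_fold"]) > np.log2(fold_threshold)) & (
        df["fdr"] < fdr_threshold
    )
    if min_rpkm is not None:
        if "rpkm" not in df.columns:
            raise ValueError("min_rpkm requested but DE table has no rpkm column")
        is_de &= df["rpkm"] > min_rpkm
    df["is_de"] = is_de
    return df
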