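"""Promoter occupancy, Venn overlaps, bivalency, and sample correlation.

A gene's promoter is "occupied" by a peak set when any peak overlaps the
+-window around its TSS by at least 1 bp.  Bivalent genes carry both
H3K4me3 and H3K27me3 at the promoter.  The sample-sample similarity matrix
is Pearson correlation of log2 promoter densities with average-linkage
hierarchical clustering — a structural substitute for self-organizing-map
affinity clustering, comparable in layout but not numerically.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .coverage import interval_densities
from .genome_io import GeneAnnotation, PeakSet, TagCollection

__all__ = [
    "promoter_occupancy",
    "venn_counts",
    "bivalent_genes",
    "promoter_density_matrix",
    "correlate_and_cluster",
]

DEFAULT_OCCUPANCY_WINDOW = 2000


def promoter_occupancy(
    peaks: PeakSet,
    genes: GeneAnnotation,
    window: int = DEFAULT_OCCUPANCY_WINDOW,
) -> pd.Series:
    """Boolean per gene: does any peak overlap [tss-window, tss+window)?"""
    if window <= 0:
        raise ValueError("window must be > 0")
    ids = []
    occ = []
    for gene in genes:
        start = max(gene.tss - window, 0)
        end = gene.tss + window
        ids.append(gene.gene_id)
        occ.append(bool(peaks.overlapping(gene.chrom, start, end)))
    return pd.Series(occ, index=pd.Index(ids, name="gene_id"), name=peaks.name)


def venn_counts(sets: Mapping[str, Sequence[bool]]) -> dict[str, int]:
    """Exclusive region counts for 2-4 named boolean vectors.

    Keys are '&'-joined member names for each non-empty combination, plus
    'none' for elements in no set.  Counts sum to the universe size.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts requires 2-4 sets")
    arrays = [np.asarray(sets[n], dtype=bool) for n in names]
    n = len(arrays[0])
    for name, arr in zip(names, arrays):
        if len(arr) != n:
            raise ValueError(f"set {name!r} has mismatched length")
    counts: dict[str, int] = {}
    for mask_bits in range(2 ** len(names)):
        member = np.ones(n, dtype=bool)
        included = []
        for i, name in enumerate(names):
            if mask_bits >> i & 1:
                member &= arrays[i]
                included.append(name)
            else:
                member &= ~arrays[i]
        key = "&".join(included) if included else "none"
        counts[key] = int(member.sum())
    return counts


def bivalent_genes(k4_occupancy: pd.Series, k27_occupancy: pd.Series) -> pd.Series:
    """Genes whose promoter carries both H3K4me3 and H3K27me3."""
    if not k4_occupancy.index.equals(k27_occupancy.index):
        raise ValueError("occupancy vectors cover different gene universes")
    out = k4_occupancy & k27_occupancy
    out.name = "bivalent"
    return out


def promoter_density_matrix(
    samples: Sequence[TagCollection],
    genes: GeneAnnotation,
    window: int = DEFAULT_OCCUPANCY_WINDOW,
) -> pd.DataFrame:
    """Genes x samples matrix of promoter RPBM densities (+-window of TSS)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    ids = [g.gene_id for g in genes]
    chroms = np.asarray([g.chrom for g in genes])
    starts = np.asarray([max(g.tss - window, 0) for g in genes], dtype=np.int64)
    ends = np.asarray([g.tss + window for g in genes], dtype=np.int64)
    cols = {}
    for tags in samples:
        dens = np.empty(len(ids))
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            dens[sel] = interval_densities(tags, chrom, starts[sel], ends[sel])
        cols[tags.sample_id] = dens
    return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        left, right, height, _ = link[i - n]
        return f"({node(int(left))},{node(int(right))}):{height:.6g}"

    return node(2 * n - 2) + ";"


def correlate_and_cluster(
    matrix: pd.DataFrame, pseudocount: float = 0.1
) -> tuple[pd.DataFrame, list[str], str]:
    """Pearson correlation of log2 promoter densities + average-linkage tree.

    Returns (correlation matrix, deterministic leaf order, Newick-like
    dendrogram string).  Distance is 1 - r.  A constant column has undefined
    correlation and raises an error naming the sample.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    logged = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    stds = logged.std(axis=0)
    for name, s in zip(matrix.columns, stds):
        if s == 0:
            raise ValueError(
                f"sample {name!r} has constant promoter density; "
                "correlation undefined"
            )
    corr = np.corrcoef(logged, rowvar=False)
    corr_df = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    leaf_order = [matrix.columns[i] for i in leaves]
    newick = _linkage_to_newick(link, list(matrix.columns))
    return corr_df, leaf_order, newick
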