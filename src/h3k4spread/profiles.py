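"""Anchor-centred and length-scaled metagene profiles.

All profile rows are oriented so that "downstream" of the anchor is to the
right regardless of feature strand; genes are weighted equally (not by tag
count) when averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneAnnotation, TagCollection

__all__ = [
    "ProfileMatrix",
    "anchor_profile",
    "metagene_profile",
    "stratify_by_expression",
    "fold_change_profile",
]

DEFAULT_FLANK = 5000
DEFAULT_BIN = 100
DEFAULT_BODY_BINS = 100


@dataclass
class ProfileMatrix:
    """Feature x position matrix of RPBM densities."""

    feature_ids: list[str]
    positions: list[str]
    values: np.ndarray
    anchor_kind: str  # TSS | TES | center | scaled_gene
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.feature_ids), len(self.positions)):
            raise ValueError("matrix dimensions do not match ids x positions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def mean_profile(self) -> np.ndarray:
        """Column means: the average profile curve (equal gene weighting)."""
        return self.values.mean(axis=0)

    def subset(self, feature_ids: Sequence[str]) -> "ProfileMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        return ProfileMatrix(
            list(feature_ids), self.positions, self.values[rows], self.anchor_kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.positions
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def anchor_profile(
    tags: TagCollection,
    anchors: Sequence[tuple[str, int, str]],
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
    anchor_ids: Sequence[str] | None = None,
    anchor_kind: str = "center",
) -> ProfileMatrix:
    """Profile of RPBM densities in fixed bins around anchor points.

    ``anchors`` are (chrom, position, strand) triples; rows for minus-strand
    anchors are reversed so downstream is rightward.  Anchors on chromosomes
    unknown to the tag collection are skipped with a warning and reported in
    ``excluded``; anchors whose window would run past the chromosome start
    are clipped bin-wise.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    all_ids = list(anchor_ids) if anchor_ids is not None else [
        f"anchor_{i}" for i in range(len(anchors))
    ]
    if len(all_ids) != len(anchors):
        raise ValueError("anchor_ids length mismatch")
    known = set(tags.chromosomes)
    keep = [i for i, a in enumerate(anchors) if a[0] in known]
    skipped = [all_ids[i] for i, a in enumerate(anchors) if a[0] not in known]
    if skipped:
        warnings.warn(
            f"{len(skipped)} anchors on chromosomes without tags; skipped",
            stacklevel=2,
        )
    anchors = [anchors[i] for i in keep]
    ids = [all_ids[i] for i in keep]
    offsets = np.arange(n_bins, dtype=np.int64) * bin_size - flank
    values = np.zeros((len(anchors), n_bins))
    scale = tags.library_size / 1e6
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _, _) in enumerate(anchors):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, rows in by_chrom.items():
        pos = np.asarray([anchors[i][1] for i in rows], dtype=np.int64)
        starts = (pos[:, None] + offsets[None, :]).ravel()
        ends = starts + bin_size
        clipped_starts = np.maximum(starts, 0)
        ov = np.zeros(len(starts), dtype=np.int64)
        valid = ends > 0
        if valid.any():
            ov[valid] = tags.overlap_bp(chrom, clipped_starts[valid], ends[valid])
        dens = (ov / bin_size / scale).reshape(len(rows), n_bins)
        values[rows, :] = dens
    for i, (_, _, strand) in enumerate(anchors):
        if strand == "-":
            values[i] = values[i, ::-1]
    positions = [str(int(o + bin_size // 2)) for o in offsets]
    return ProfileMatrix(ids, positions, values, anchor_kind, excluded=skipped)


def metagene_profile(
    tags: TagCollection,
    genes: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
    n_body_bins: int = DEFAULT_BODY_BINS,
) -> ProfileMatrix:
    """Length-scaled TSS->TES profile with fixed flanks.

    Fixed ``flank`` bp (in ``bin_size`` bins) upstream of the TSS and
    downstream of the TES; the gene body is divided into ``n_body_bins``
    equal-length bins per gene.  Genes shorter than ``n_body_bins`` bp are
    excluded and reported in ``excluded``.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_flank = flank // bin_size
    scale = tags.library_size / 1e6
    kept: list[str] = []
    excluded: list[str] = []
    rows: list[np.ndarray] = []
    for gene in genes:
        if gene.length < n_body_bins:
            excluded.append(gene.gene_id)
            continue
        kept.append(gene.gene_id)
        iv = gene.interval
        body_edges = np.linspace(iv.start, iv.end, n_body_bins + 1)
        body_starts = np.floor(body_edges[:-1]).astype(np.int64)
        body_ends = np.floor(body_edges[1:]).astype(np.int64)
        body_ends = np.maximum(body_ends, body_starts + 1)
        left_starts = iv.start - flank + np.arange(n_flank, dtype=np.int64) * bin_size
        left_ends = left_starts + bin_size
        right_starts = iv.end + np.arange(n_flank, dtype=np.int64) * bin_size
        right_ends = right_starts + bin_size
        starts = np.concatenate([left_starts, body_starts, right_starts])
        ends = np.concatenate([left_ends, body_ends, right_ends])
        clipped = np.maximum(starts, 0)
        ov = np.zeros(len(starts), dtype=np.int64)
        valid = ends > 0
        ov[valid] = tags.overlap_bp(gene.chrom, clipped[valid], ends[valid])
        dens = ov / (ends - starts) / scale
        if gene.strand == "-":
            dens = dens[::-1]
        rows.append(dens)
    positions = (
        [f"up_{-(flank - i * bin_size - bin_size // 2)}" for i in range(n_flank)]
        + [f"body_{j}" for j in range(n_body_bins)]
        + [f"down_{i * bin_size + bin_size // 2}" for i in range(n_flank)]
    )
    values = (
        np.vstack(rows) if rows else np.empty((0, 2 * n_flank + n_body_bins))
    )
    return ProfileMatrix(kept, positions, values, "scaled_gene", excluded=excluded)


def stratify_by_expression(
    gene_ids: Sequence[str],
    expression: Mapping[str, float],
    k: int = 4,
) -> list[list[str]]:
    """Split genes into k equal-size groups by descending expression.

    Group 0 is the highest-expressed (the "highest 25%" when k=4).  The
    remainder goes to the last group; ties break by gene_id.  Genes missing
    from ``expression`` are excluded (with a warning).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    missing = [g for g in gene_ids if g not in expression]
    if missing:
        warnings.warn(
            f"{len(missing)} genes missing expression values; excluded",
            stacklevel=2,
        )
    ranked = sorted(
        (g for g in gene_ids if g in expression),
        key=lambda g: (-expression[g], g),
    )
    n = len(ranked)
    size = n // k
    groups = [ranked[i * size:(i + 1) * size] for i in range(k - 1)]
    groups.append(ranked[(k - 1) * size:])
    return groups


def fold_change_profile(
    profile_a: ProfileMatrix,
    profile_b: ProfileMatrix,
    pseudocount: float = 0.1,
) -> np.ndarray:
    """Per-position log2((mean_B + p)/(mean_A + p)) average fold-change curve.

    Convention: A is the control condition (e.g. shLuc), B the perturbation
    (e.g. shKdm5b), so positive values mean signal gained after perturbation.
    """
    if profile_a.positions != profile_b.positions:
        raise ValueError("profiles have mismatched positions")
    if profile_a.feature_ids != profile_b.feature_ids:
        raise ValueError("profiles have mismatched feature sets")
    mean_a = profile_a.mean_profile()
    mean_b = profile_b.mean_profile()
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
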