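"""Genomic data model and file I/O.

Coordinate convention: 0-based, half-open ``[start, end)`` everywhere
internally (BED native; GTF converted on read).  ChIP tags are stored as
strand-aware 5' read positions and are extended ``fragment_extension`` bp in
their strand direction before any base-pair counting, as a proxy for the
sequenced fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneAnnotation",
    "MarkKind",
    "TagCollection",
    "Peak",
    "PeakSet",
    "ShortGeneError",
    "read_tags_bed",
    "read_gene_annotation",
    "read_peaks_bed",
    "promoter_window",
    "gene_body_window",
]

DEFAULT_FRAGMENT_EXTENSION = 150


class ShortGeneError(ValueError):
    """Raised when a gene is too short to have a non-empty gene-body window."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MarkKind:
    """A chromatin mark (or TF) and its promoter-window half-width in bp.

    The promoter bin is a 1 kb / 1.5 kb / 3 kb window centred on the TSS for
    genes marked by H3K4me3 / H3K4me2 / H3K4me1 respectively; other marks
    default to +-2 kb (configurable).
    """

    name: str
    promoter_halfwidth: int

    _DEFAULT_HALFWIDTH = {
        "H3K4me3": 500,
        "H3K4me2": 750,
        "H3K4me1": 1500,
    }
    _FALLBACK_HALFWIDTH = 2000

    def __post_init__(self) -> None:
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be > 0")

    @classmethod
    def from_name(cls, name: str, promoter_halfwidth: int | None = None) -> "MarkKind":
        if promoter_halfwidth is None:
            promoter_halfwidth = cls._DEFAULT_HALFWIDTH.get(
                name, cls._FALLBACK_HALFWIDTH
            )
        return cls(name=name, promoter_halfwidth=promoter_halfwidth)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, exon structure, and derived TSS/TES anchors."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            object.__setattr__(self, "exons", (replace(self.interval),))
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def exon_length(self) -> int:
        return sum(ex.length for ex in self.exons)


class GeneAnnotation:
    """A collection of :class:`GeneModel` with a per-chromosome sorted index."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.interval.start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chromosome(self, chrom: str) -> list[GeneModel]:
        return list(self._by_chrom.get(chrom, []))

    def write_bed12(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self:
                iv = g.interval
                sizes = ",".join(str(ex.length) for ex in g.exons) + ","
                starts = ",".join(str(ex.start - iv.start) for ex in g.exons) + ","
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            iv.chrom, iv.start, iv.end, g.gene_id, 0, iv.strand,
                            iv.start, iv.end, "0,0,0", len(g.exons), sizes, starts,
                        )
                    )
                    + "\n"
                )


class TagCollection:
    """Strand-aware 5' read positions per chromosome, plus library size.

    Tags are extended ``fragment_extension`` bp in their strand direction
    when counted; all fragments therefore have the same length.  Fragments
    that would run off the chromosome start are shifted to begin at 0 so the
    constant fragment length is preserved.
    """

    def __init__(
        self,
        sample_id: str,
        tags: Mapping[str, tuple[np.ndarray, np.ndarray]],
        fragment_extension: int = DEFAULT_FRAGMENT_EXTENSION,
        library_size: int | None = None,
    ):
        if fragment_extension < 1:
            raise ValueError("fragment_extension must be >= 1")
        self.sample_id = sample_id
        self.fragment_extension = int(fragment_extension)
        self.tags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        n_total = 0
        for chrom, (pos, strand) in tags.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            if pos.shape != strand.shape:
                raise ValueError("positions and strands must have equal length")
            order = np.argsort(pos, kind="stable")
            self.tags[chrom] = (pos[order], strand[order])
            n_total += len(pos)
        self.n_tags = n_total
        if library_size is None:
            library_size = n_total
        if library_size < 1:
            raise ValueError("library_size must be >= 1")
        self.library_size = int(library_size)
        self._frag_starts: dict[str, np.ndarray] = {}
        self._frag_prefix: dict[str, np.ndarray] = {}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.tags)

    def fragment_starts(self, chrom: str) -> np.ndarray:
        """Sorted extended-fragment start positions on ``chrom``."""
        if chrom not in self._frag_starts:
            if chrom not in self.tags:
                self._frag_starts[chrom] = np.empty(0, dtype=np.int64)
            else:
                pos, strand = self.tags[chrom]
                fs = np.where(strand >= 0, pos, pos - self.fragment_extension + 1)
                fs = np.maximum(fs, 0)
                fs.sort()
                self._frag_starts[chrom] = fs
            starts = self._frag_starts[chrom]
            pref = np.zeros(len(starts) + 1, dtype=np.int64)
            np.cumsum(starts, out=pref[1:])
            self._frag_prefix[chrom] = pref
        return self._frag_starts[chrom]

    def overlap_bp(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Total extended-tag bp overlapping each query interval.

        Vectorised over queries; exact (no binning).  Relies on all fragments
        having the same length L: fragments are split into left-partial,
        fully-overlapping, and right-partial groups via searchsorted on the
        sorted start array, and summed with prefix sums.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        fs = self.fragment_starts(chrom)
        pref = self._frag_prefix[chrom]
        out = np.zeros(starts.shape, dtype=np.int64)
        if len(fs) == 0:
            return out
        L = self.fragment_extension
        c1 = np.minimum(starts, ends - L)
        c2 = np.maximum(starts, ends - L)
        i0 = np.searchsorted(fs, starts - L, side="right")
        i1 = np.searchsorted(fs, c1, side="right")
        i2 = np.searchsorted(fs, c2, side="right")
        i3 = np.searchsorted(fs, ends, side="left")
        # fragments in (start-L, c1]: overlap = f + L - start
        out += (pref[i1] - pref[i0]) + (L - starts) * (i1 - i0)
        # fragments in (c1, c2]: constant overlap min(len, L)
        out += (i2 - i1) * np.minimum(ends - starts, L)
        # fragments in (c2, end): overlap = end - f
        out += ends * (i3 - i2) - (pref[i3] - pref[i2])
        return out

    def max_fragment_end(self, chrom: str) -> int:
        fs = self.fragment_starts(chrom)
        return int(fs[-1]) + self.fragment_extension if len(fs) else 0

    def with_library_size(self, library_size: int) -> "TagCollection":
        return TagCollection(
            self.sample_id, self.tags, self.fragment_extension, library_size
        )

    def concatenate(self, other: "TagCollection", sample_id: str | None = None) -> "TagCollection":
        """Merge two collections (e.g. a library with a duplicate of itself)."""
        if other.fragment_extension != self.fragment_extension:
            raise ValueError("fragment_extension mismatch")
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in set(self.tags) | set(other.tags):
            parts = [t[chrom] for t in (self.tags, other.tags) if chrom in t]
            merged[chrom] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        return TagCollection(
            sample_id or self.sample_id, merged, self.fragment_extension
        )

    def write_bed(self, path: str | Path) -> None:
        """Write tags as 6-column BED (1 bp records at the 5' position)."""
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                pos, strand = self.tags[chrom]
                for p, s in zip(pos, strand):
                    if s >= 0:
                        fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t+\n")
                    else:
                        fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t-\n")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("peak score must be finite")

    @property
    def summit_position(self) -> int:
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


class PeakSet:
    """A named, per-chromosome-sorted set of scored peaks."""

    def __init__(self, name: str, peaks: Iterable[Peak]):
        self.name = name
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        self._trees: dict[str, "object"] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def _build_trees(self):
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for i, p in enumerate(self.peaks):
            trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end, i
            )
        self._trees = trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[Peak]:
        """Peaks overlapping ``[start, end)`` by >= 1 bp."""
        if self._trees is None:
            self._build_trees()
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.peaks[iv.data] for iv in sorted(tree.overlap(start, end))]

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks):
                iv = p.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{self.name}_{i}\t{p.score:g}\t.\n"
                )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_bed_fields(line: str, lineno: int, path) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        fields = line.split()
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: BED record has fewer than 3 columns")
    return fields


def read_tags_bed(
    path: str | Path, fragment_extension: int = DEFAULT_FRAGMENT_EXTENSION,
    sample_id: str | None = None,
) -> TagCollection:
    """Read aligned-read BED into a :class:`TagCollection`.

    The 5' position of a record is its ``start`` on the + strand and
    ``end - 1`` on the - strand.  Records with fewer than 6 columns default
    to the + strand.  ``library_size`` is the number of records.
    """
    path = Path(path)
    per_chrom_pos: dict[str, list[int]] = {}
    per_chrom_strand: dict[str, list[int]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_fields(line, lineno, path)
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if strand == "+":
                pos, sgn = start, 1
            else:
                pos, sgn = end - 1, -1
            per_chrom_pos.setdefault(chrom, []).append(pos)
            per_chrom_strand.setdefault(chrom, []).append(sgn)
            n += 1
    if n == 0:
        raise ValueError(f"{path}: no tag records found")
    tags = {
        chrom: (
            np.asarray(per_chrom_pos[chrom], dtype=np.int64),
            np.asarray(per_chrom_strand[chrom], dtype=np.int8),
        )
        for chrom in per_chrom_pos
    }
    return TagCollection(
        sample_id or path.stem, tags, fragment_extension=fragment_extension
    )


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            n_exons = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_exons or len(offsets) != n_exons:
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                )
            )
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    # Collect exon features per gene_id; gene extent = exon union span.
    exons_by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GTF requires 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: exon without gene_id")
            if gene_id not in exons_by_gene:
                order.append(gene_id)
            # GTF is 1-based inclusive; convert to 0-based half-open.
            exons_by_gene.setdefault(gene_id, []).append(
                (chrom, int(start) - 1, int(end), strand)
            )
    if not exons_by_gene:
        raise ValueError(f"{path}: no exon features found")
    genes = []
    for gene_id in order:
        exs = exons_by_gene[gene_id]
        chroms = {e[0] for e in exs}
        strands = {e[3] for e in exs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id}: exons on multiple chromosomes/strands")
        chrom, strand = exs[0][0], exs[0][3]
        # exon union
        merged: list[list[int]] = []
        for _, s, e, _ in sorted(exs, key=lambda x: x[1]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        interval = GenomicInterval(chrom, merged[0][0], merged[-1][1], strand)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=interval,
                exons=tuple(
                    GenomicInterval(chrom, s, e, strand) for s, e in merged
                ),
            )
        )
    return genes


def read_gene_annotation(path: str | Path, dialect: str = "BED12") -> GeneAnnotation:
    """Read a gene annotation in BED12 or GTF dialect.

    BED12 yields one :class:`GeneModel` per record (transcript); GTF yields
    one per ``gene_id`` with the exon union.  Duplicate gene_ids are an
    error.
    """
    path = Path(path)
    if dialect.upper() == "BED12":
        genes = _read_bed12(path)
    elif dialect.upper() == "GTF":
        genes = _read_gtf(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return GeneAnnotation(genes)


def read_peaks_bed(path: str | Path, name: str | None = None) -> PeakSet:
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_fields(line, lineno, path)
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) >= 5 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed peak record") from exc
            peaks.append(
                Peak(interval=GenomicInterval(fields[0], start, end), score=score)
            )
    return PeakSet(name or path.stem, peaks)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneModel, mark: MarkKind) -> GenomicInterval:
    """Symmetric promoter bin around the TSS, clipped at the chromosome start."""
    hw = mark.promoter_halfwidth
    start = max(gene.tss - hw, 0)
    return GenomicInterval(gene.chrom, start, gene.tss + hw, gene.strand)


def gene_body_window(gene: GeneModel, mark: MarkKind) -> GenomicInterval:
    """Strand-aware region from the promoter bin's downstream edge to the TES.

    Raises :class:`ShortGeneError` when the body would be empty; such genes
    are excluded from spreading-index analyses.
    """
    hw = mark.promoter_halfwidth
    if gene.length <= hw:
        raise ShortGeneError(
            f"gene {gene.gene_id} (length {gene.length}) too short for "
            f"{mark.name} body window (promoter halfwidth {hw})"
        )
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tss + hw, gene.tes, "+")
    return GenomicInterval(gene.chrom, gene.tes, gene.tss - hw, "-")
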