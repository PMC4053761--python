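"""Synthetic ChIP-seq / RNA-seq generator with ground truth.

Emulates the statistical structure the analysis assumes, so every pipeline
stage is testable without any sequencing download:

* promoter-peaked H3K4 methylation (Gaussian around the TSS) with a
  condition-dependent fraction of each gene's signal spread uniformly over
  the gene body (more spreading after demethylase knockdown);
* enhancer-centred signal with condition-dependent shore spreading, and
  H3K27ac core mass coupled negatively to the shore-fraction increase;
* negative-binomial expression counts where the probability of differential
  expression increases with the gene's true spreading change.

All randomness flows from one master seed through named child streams, so
identical parameters and seed give byte-identical outputs.  Ground truth
(per-gene spread fractions, DE flags and effect sizes; per-enhancer shore
fractions and acetylation scaling) is recorded for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .genome_io import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    MarkKind,
    Peak,
    PeakSet,
    TagCollection,
)

__all__ = ["SimulationParams", "SyntheticDataset"]

H3K4_MARKS = ("H3K4me3", "H3K4me2", "H3K4me1")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic genome/ChIP/expression model."""

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 25_000_000
    n_genes: int = 2000
    gene_length_median: int = 10_000
    gene_length_sigma: float = 0.5  # log-scale sd
    min_gene_length: int = 2_000
    max_gene_length: int = 80_000
    min_gene_gap: int = 10_000
    gap_jitter_mean: float = 2_000.0
    # gene ChIP
    library_size: int = 2_000_000
    background_rate: float = 0.01  # tags per bp of genome
    fragment_extension: int = 150
    conditions: tuple[str, ...] = ("control", "knockdown")
    spread_fraction: tuple[float, ...] = (0.1, 0.4)  # per condition
    spread_multiplier_sigma: float = 0.35  # per-gene lognormal multiplier
    max_spread_fraction: float = 1.0
    # enhancers
    n_enhancers: int = 1000
    enhancer_library_size: int = 1_000_000
    enhancer_core_sd: float = 250.0
    enhancer_margin: int = 4_000  # min distance to genes and between enhancers
    enhancer_mass_sigma: float = 0.7
    shore_outer: int = 2_000
    shore_fraction: tuple[float, ...] = (0.1, 0.4)  # per condition
    shore_multiplier_sigma: float = 0.35
    max_shore_fraction: float = 1.0
    h3k27ac_coupling: float = -3.0  # gamma <= 0: ac mass *= exp(gamma*dshore)
    # expression
    counts_library_size: int = 3_000_000
    expression_sigma: float = 1.0  # lognormal baseline
    nb_dispersion: float = 0.01
    de_alpha: float = -2.2  # logit baseline DE probability
    de_beta: float = 3.0  # DE log-odds per unit normalized dspread rank
    de_lfc_low: float = 0.6
    de_lfc_high: float = 2.0

    def __post_init__(self) -> None:
        if self.library_size < 10_000:
            raise ValueError("library_size must be >= 10^4")
        if len(self.spread_fraction) != len(self.conditions):
            raise ValueError("one spread_fraction per condition required")
        if len(self.shore_fraction) != len(self.conditions):
            raise ValueError("one shore_fraction per condition required")
        for s in (*self.spread_fraction, *self.shore_fraction):
            if not 0 <= s <= 1:
                raise ValueError("spread/shore fractions must lie in [0, 1]")
        if self.h3k27ac_coupling > 0:
            raise ValueError("h3k27ac_coupling must be <= 0")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None


# stream ids for the per-operation child generators
_S_GENOME, _S_TRUTH, _S_CHIP, _S_ENH_CHIP, _S_COUNTS = 0, 1, 2, 3, 4
_MARK_INDEX = {m: i for i, m in enumerate((*H3K4_MARKS, "H3K27ac"))}


class SyntheticDataset:
    """A generated genome + ground truth, with tag/count emitters."""

    def __init__(
        self,
        params: SimulationParams,
        annotation: GeneAnnotation,
        enhancers: PeakSet,
        gene_truth: pd.DataFrame,
        enhancer_truth: pd.DataFrame,
    ):
        self.params = params
        self.annotation = annotation
        self.enhancers = enhancers
        self.gene_truth = gene_truth
        self.enhancer_truth = enhancer_truth

    # -- construction -----------------------------------------------------

    @classmethod
    def generate(cls, params: SimulationParams) -> "SyntheticDataset":
        annotation = _simulate_genome(params)
        enhancers = _place_enhancers(params, annotation)
        gene_truth = _gene_truth(params, annotation)
        enhancer_truth = _enhancer_truth(params, enhancers)
        return cls(params, annotation, enhancers, gene_truth, enhancer_truth)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        p = self.params
        return {f"chr{i + 1}": p.chromosome_length for i in range(p.n_chromosomes)}

    # -- ChIP tags --------------------------------------------------------

    def chip_tags(self, condition: str, mark: str) -> TagCollection:
        """Gene-centred ChIP tags: background + promoter/body mixture.

        Per-gene signal mass is proportional to the gene's expression rank;
        a fraction s_g (condition spread fraction x per-gene multiplier) of
        it is spread uniformly over the gene body, the rest is Gaussian
        around the TSS with sd = half the mark's promoter half-width.
        """
        p = self.params
        ci = p.condition_index(condition)
        rng = p.rng(_S_CHIP, ci, _MARK_INDEX[mark])
        mark_kind = MarkKind.from_name(mark)
        genome_len = p.n_chromosomes * p.chromosome_length
        n_bg = int(round(p.background_rate * genome_len))
        if n_bg >= p.library_size:
            raise ValueError("background_rate leaves no signal tags")
        n_signal = p.library_size - n_bg

        truth = self.gene_truth
        weights = truth["mass_weight"].to_numpy()
        per_gene = rng.multinomial(n_signal, weights / weights.sum())
        s_g = truth[f"spread_{condition}"].to_numpy().copy()

        genes = [self.annotation[g] for g in truth.index]
        tss = np.asarray([g.tss for g in genes], dtype=np.int64)
        chrom_ids = np.asarray(
            [int(g.chrom[3:]) - 1 for g in genes], dtype=np.int64
        )
        # body window: promoter-bin downstream edge to the TES
        hw = mark_kind.promoter_halfwidth
        g_start = np.asarray([g.interval.start for g in genes], dtype=np.int64)
        g_end = np.asarray([g.interval.end for g in genes], dtype=np.int64)
        plus = np.asarray([g.strand == "+" for g in genes])
        body_start = np.where(plus, g_start + hw, g_start)
        body_len = np.where(plus, g_end - g_start - hw, g_end - hw - g_start)
        s_g[body_len <= 0] = 0.0  # short genes: no body to spread into

        n_body = rng.binomial(per_gene, s_g)
        n_prom = per_gene - n_body
        # promoter component
        prom_centers = rng.normal(
            np.repeat(tss, n_prom),
            mark_kind.promoter_halfwidth / 2.0,
        )
        prom_chroms = np.repeat(chrom_ids, n_prom)
        # gene-body component (uniform over the body window)
        body_centers = (
            np.repeat(body_start, n_body)
            + rng.random(int(n_body.sum()))
            * np.repeat(np.maximum(body_len, 1), n_body)
        )
        body_chroms = np.repeat(chrom_ids, n_body)
        # background
        bg_chroms = rng.integers(0, p.n_chromosomes, n_bg)
        bg_centers = rng.random(n_bg) * p.chromosome_length

        centers = np.concatenate([prom_centers, body_centers, bg_centers])
        chroms = np.concatenate([prom_chroms, body_chroms, bg_chroms])
        return self._centers_to_tags(
            f"{mark}_{condition}", centers, chroms, rng, p.library_size
        )

    def enhancer_tags(self, condition: str, mark: str) -> TagCollection:
        """Enhancer-centred ChIP tags for H3K4me1/2/3 or H3K27ac.

        H3K4 marks: core Gaussian + uniform shore mixture with per-enhancer
        shore fraction.  H3K27ac: core only, with per-enhancer mass scaled
        by exp(gamma * (shore fraction - control shore fraction)).
        """
        p = self.params
        ci = p.condition_index(condition)
        rng = p.rng(_S_ENH_CHIP, ci, _MARK_INDEX[mark])
        genome_len = p.n_chromosomes * p.chromosome_length
        n_bg = int(round(p.background_rate * genome_len))
        if n_bg >= p.enhancer_library_size:
            raise ValueError("background_rate leaves no signal tags")
        n_signal = p.enhancer_library_size - n_bg

        truth = self.enhancer_truth
        summits = truth["summit"].to_numpy(np.int64)
        chrom_ids = truth["chrom_id"].to_numpy(np.int64)
        mass = truth["mass_weight"].to_numpy().copy()
        f_cond = truth[f"shore_{condition}"].to_numpy()
        if mark == "H3K27ac":
            dshore = f_cond - truth[f"shore_{p.conditions[0]}"].to_numpy()
            mass = mass * np.exp(p.h3k27ac_coupling * dshore)
            shore_frac = np.zeros(len(mass))
        else:
            shore_frac = f_cond
        per_enh = rng.multinomial(n_signal, mass / mass.sum())
        n_shore = rng.binomial(per_enh, shore_frac)
        n_core = per_enh - n_shore

        core_centers = rng.normal(
            np.repeat(summits, n_core).astype(float), p.enhancer_core_sd
        )
        core_chroms = np.repeat(chrom_ids, n_core)
        # shores: uniform over the two flanking bands
        chw = CORE_HALFWIDTH_FOR_SIM
        width = p.shore_outer - chw
        u = rng.random(int(n_shore.sum())) * 2.0 - 1.0  # in [-1, 1)
        offs = np.where(u < 0, -chw + u * width, chw + u * width)
        shore_centers = np.repeat(summits, n_shore) + offs
        shore_chroms = np.repeat(chrom_ids, n_shore)

        bg_chroms = rng.integers(0, p.n_chromosomes, n_bg)
        bg_centers = rng.random(n_bg) * p.chromosome_length

        centers = np.concatenate([core_centers, shore_centers, bg_centers])
        chroms = np.concatenate([core_chroms, shore_chroms, bg_chroms])
        return self._centers_to_tags(
            f"enh_{mark}_{condition}", centers, chroms, rng,
            p.enhancer_library_size,
        )

    def _centers_to_tags(
        self,
        sample_id: str,
        centers: np.ndarray,
        chrom_ids: np.ndarray,
        rng: np.random.Generator,
        library_size: int,
    ) -> TagCollection:
        p = self.params
        ext = p.fragment_extension
        strands = rng.integers(0, 2, len(centers)).astype(np.int8) * 2 - 1
        pos = np.where(
            strands > 0,
            np.round(centers).astype(np.int64) - ext // 2,
            np.round(centers).astype(np.int64) + ext // 2 - 1,
        )
        pos = np.clip(pos, 0, p.chromosome_length - 1)
        tags = {}
        for c in range(p.n_chromosomes):
            sel = chrom_ids == c
            tags[f"chr{c + 1}"] = (pos[sel], strands[sel])
        return TagCollection(
            sample_id, tags, fragment_extension=ext, library_size=library_size
        )

    def input_tags(self, library_size: int | None = None) -> TagCollection:
        """Whole-cell-extract style control: uniform background only."""
        p = self.params
        rng = p.rng(_S_CHIP, 99)
        n = library_size or p.library_size
        chroms = rng.integers(0, p.n_chromosomes, n)
        centers = rng.random(n) * p.chromosome_length
        return self._centers_to_tags("input", centers, chroms, rng, n)

    # -- expression counts -------------------------------------------------

    def counts(self, condition: str, replicate: int = 0) -> pd.Series:
        """NB gene counts for one condition (library counts_library_size)."""
        p = self.params
        ci = p.condition_index(condition)
        rng = p.rng(_S_COUNTS, ci, replicate)
        truth = self.gene_truth
        base = truth["expression"].to_numpy()
        lfc = np.where(
            truth["is_de"].to_numpy() & (ci > 0),
            truth["log2_fold"].to_numpy(),
            0.0,
        )
        mean = base * 2.0**lfc
        mean = mean / mean.sum() * p.counts_library_size
        phi = p.nb_dispersion
        if phi < 1e-9:
            draws = rng.poisson(mean)
        else:
            lam = rng.gamma(1.0 / phi, mean * phi)
            draws = rng.poisson(lam)
        return pd.Series(draws, index=truth.index, name=condition)

    def expression_table(self) -> ExpressionTable:
        cols = {c: self.counts(c) for c in self.params.conditions}
        counts = pd.DataFrame(cols).astype(np.int64)
        lengths = pd.Series(
            {g: self.annotation[g].exon_length for g in counts.index},
            name="length",
        )
        return ExpressionTable(counts=counts, exon_lengths=lengths)

    # -- output -----------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write annotation, enhancer peaks, truth tables; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "genes.bed12",
            "enhancers": outdir / "enhancers.bed",
            "gene_truth": outdir / "gene_truth.tsv",
            "enhancer_truth": outdir / "enhancer_truth.tsv",
        }
        self.annotation.write_bed12(paths["annotation"])
        self.enhancers.write_bed(paths["enhancers"])
        self.gene_truth.to_csv(paths["gene_truth"], sep="\t")
        self.enhancer_truth.to_csv(paths["enhancer_truth"], sep="\t")
        return paths


CORE_HALFWIDTH_FOR_SIM = 500  # matches the analysis-side default geometry


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _simulate_genome(params: SimulationParams) -> GeneAnnotation:
    """Place non-overlapping genes with >= min_gene_gap spacing."""
    rng = params.rng(_S_GENOME)
    lengths = np.exp(
        rng.normal(np.log(params.gene_length_median), params.gene_length_sigma,
                   params.n_genes)
    )
    lengths = np.clip(lengths, params.min_gene_length, params.max_gene_length)
    lengths = lengths.astype(np.int64)
    strands = np.where(rng.random(params.n_genes) < 0.5, "+", "-")
    gaps = params.min_gene_gap + rng.exponential(
        params.gap_jitter_mean, params.n_genes
    ).astype(np.int64)
    genes: list[GeneModel] = []
    chrom_i = 0
    cursor = int(gaps[0] // 2) + params.min_gene_gap
    for i in range(params.n_genes):
        if cursor + lengths[i] + params.min_gene_gap > params.chromosome_length:
            chrom_i += 1
            cursor = params.min_gene_gap
            if chrom_i >= params.n_chromosomes:
                raise ValueError(
                    "cannot place all genes: increase chromosome_length or "
                    "reduce n_genes/min_gene_gap"
                )
        start = cursor
        end = start + int(lengths[i])
        genes.append(
            GeneModel(
                gene_id=f"gene_{i:05d}",
                interval=GenomicInterval(
                    f"chr{chrom_i + 1}", start, end, str(strands[i])
                ),
            )
        )
        cursor = end + int(gaps[i])
    return GeneAnnotation(genes)


def _place_enhancers(params: SimulationParams, annotation: GeneAnnotation) -> PeakSet:
    """Place enhancer summits intergenically, apart from genes and each other."""
    rng = params.rng(_S_GENOME, 1)
    margin = params.enhancer_margin
    allowed: list[tuple[int, int, int]] = []  # (chrom_id, lo, hi)
    for c in range(params.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = margin
        for gene in annotation.on_chromosome(chrom):
            lo = cursor
            hi = gene.interval.start - margin
            if hi - lo > 2 * params.shore_outer:
                allowed.append((c, lo, hi))
            cursor = max(cursor, gene.interval.end + margin)
        hi = params.chromosome_length - margin
        if hi - cursor > 2 * params.shore_outer:
            allowed.append((c, cursor, hi))
    if not allowed:
        raise ValueError("no intergenic space for enhancers")
    span = np.asarray([hi - lo for _, lo, hi in allowed], dtype=float)
    placed: dict[int, list[int]] = {}
    peaks: list[Peak] = []
    attempts = 0
    while len(peaks) < params.n_enhancers:
        attempts += 1
        if attempts > 50 * params.n_enhancers:
            raise ValueError(
                "cannot place enhancers: increase chromosome_length or "
                "reduce n_enhancers"
            )
        region = rng.choice(len(allowed), p=span / span.sum())
        c, lo, hi = allowed[region]
        summit = int(rng.integers(lo + params.shore_outer, hi - params.shore_outer))
        near = placed.setdefault(c, [])
        if any(abs(summit - s) < 2 * params.shore_outer for s in near):
            continue
        near.append(summit)
        peaks.append(
            Peak(
                GenomicInterval(
                    f"chr{c + 1}",
                    summit - CORE_HALFWIDTH_FOR_SIM,
                    summit + CORE_HALFWIDTH_FOR_SIM,
                ),
                score=0.0,
                summit=summit,
            )
        )
    return PeakSet("p300", peaks)


def _gene_truth(params: SimulationParams, annotation: GeneAnnotation) -> pd.DataFrame:
    rng = params.rng(_S_TRUTH)
    ids = [g.gene_id for g in annotation]
    n = len(ids)
    expression = np.exp(rng.normal(0.0, params.expression_sigma, n))
    # signal mass proportional to ascending expression rank
    rank = np.empty(n, dtype=np.int64)
    rank[np.argsort(expression, kind="stable")] = np.arange(1, n + 1)
    mult = np.exp(rng.normal(0.0, params.spread_multiplier_sigma, n))
    truth = pd.DataFrame(
        {
            "expression": expression,
            "expression_rank": rank,
            "mass_weight": rank.astype(float),
            "spread_multiplier": mult,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    for cond, frac in zip(params.conditions, params.spread_fraction):
        truth[f"spread_{cond}"] = np.minimum(
            frac * mult, params.max_spread_fraction
        )
    first = params.conditions[0]
    last = params.conditions[-1]
    truth["delta_spread"] = truth[f"spread_{last}"] - truth[f"spread_{first}"]
    # DE probability rises with the normalized rank of the spreading change
    drank = np.empty(n)
    order = np.argsort(truth["delta_spread"].to_numpy(), kind="stable")
    drank[order] = np.arange(n) / max(n - 1, 1)
    p_de = 1.0 / (1.0 + np.exp(-(params.de_alpha + params.de_beta * drank)))
    is_de = rng.random(n) < p_de
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    lfc = sign * rng.uniform(params.de_lfc_low, params.de_lfc_high, n)
    truth["de_probability"] = p_de
    truth["is_de"] = is_de
    truth["log2_fold"] = np.where(is_de, lfc, 0.0)
    return truth


def _enhancer_truth(params: SimulationParams, enhancers: PeakSet) -> pd.DataFrame:
    rng = params.rng(_S_TRUTH, 1)
    n = len(enhancers)
    ids = [f"{enhancers.name}_{i}" for i in range(n)]
    summits = np.asarray([p.summit_position for p in enhancers], dtype=np.int64)
    chrom_ids = np.asarray(
        [int(p.interval.chrom[3:]) - 1 for p in enhancers], dtype=np.int64
    )
    mass = np.exp(rng.normal(0.0, params.enhancer_mass_sigma, n))
    mult = np.exp(rng.normal(0.0, params.shore_multiplier_sigma, n))
    truth = pd.DataFrame(
        {
            "summit": summits,
            "chrom_id": chrom_ids,
            "mass_weight": mass,
            "shore_multiplier": mult,
        },
        index=pd.Index(ids, name="enhancer_id"),
    )
    for cond, frac in zip(params.conditions, params.shore_fraction):
        truth[f"shore_{cond}"] = np.minimum(
            frac * mult, params.max_shore_fraction
        )
    first = params.conditions[0]
    last = params.conditions[-1]
    truth["delta_shore"] = truth[f"shore_{last}"] - truth[f"shore_{first}"]
    truth["log2_ac_scaling"] = (
        params.h3k27ac_coupling * truth["delta_shore"] / np.log(2.0)
    )
    return truth
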