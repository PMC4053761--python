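"""The spreading index (SI) and its downstream statistics.

The SI of a gene is the ratio of H3K4-methylation density in the gene body
(promoter-bin downstream edge to the TES) to the density in the promoter bin
(1 / 1.5 / 3 kb window around the TSS for H3K4me3 / me2 / me1).  An SI
increase means methylation has spread away from the promoter into the
transcribed region.  Condition shifts in the SI distribution are assessed
with ECDFs and the two-sample Kolmogorov-Smirnov test; coupling between SI
change and differential expression (or bivalency) is summarised with
sliding-window fractions over SI-fold-change-ranked genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.distributions.empirical_distribution import ECDF as _SMECDF

from .coverage import interval_densities
from .genome_io import (
    GeneAnnotation,
    GeneModel,
    MarkKind,
    PeakSet,
    ShortGeneError,
    TagCollection,
    gene_body_window,
    promoter_window,
)

__all__ = [
    "SpreadingRecord",
    "SlidingWindowSeries",
    "spreading_index",
    "spreading_table",
    "si_fold_change",
    "ecdf",
    "ks_two_sample",
    "sliding_window_fraction",
    "classify_delta_h3k4me3",
]

PROMOTER_FLOOR = 0.05  # RPBM floor for the SI denominator
FOLD_PSEUDOCOUNT = 0.05  # additive pseudocount for SI fold changes


@dataclass(frozen=True)
class SpreadingRecord:
    """Per-gene promoter density, body density, and spreading index (RPBM)."""

    gene_id: str
    mark: str
    condition: str
    promoter_density: float
    body_density: float
    si: float


def spreading_index(
    tags: TagCollection,
    gene: GeneModel,
    mark: MarkKind,
    condition: str = "",
    floor: float = PROMOTER_FLOOR,
) -> SpreadingRecord:
    """SI of one gene: body density / max(promoter density, floor).

    Raises :class:`ShortGeneError` for genes whose body window is empty.
    """
    prom = promoter_window(gene, mark)
    body = gene_body_window(gene, mark)  # raises ShortGeneError if empty
    scale = tags.library_size / 1e6
    prom_ov = tags.overlap_bp(
        gene.chrom, np.asarray([prom.start]), np.asarray([prom.end])
    )[0]
    body_ov = tags.overlap_bp(
        gene.chrom, np.asarray([body.start]), np.asarray([body.end])
    )[0]
    prom_d = (prom_ov / prom.length) / scale
    body_d = (body_ov / body.length) / scale
    return SpreadingRecord(
        gene_id=gene.gene_id,
        mark=mark.name,
        condition=condition,
        promoter_density=prom_d,
        body_density=body_d,
        si=body_d / max(prom_d, floor),
    )


def spreading_table(
    tags: TagCollection,
    genes: GeneAnnotation,
    mark: MarkKind,
    condition: str = "",
    floor: float = PROMOTER_FLOOR,
    require_peaks: PeakSet | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Vectorised SI table for all genes of an annotation.

    Returns (table indexed by gene_id with promoter_density / body_density /
    si columns, list of excluded gene_ids).  Exclusions: short genes (empty
    body window) and, when ``require_peaks`` is given, genes whose promoter
    window does not overlap any peak of the mark.
    """
    excluded: list[str] = []
    ids: list[str] = []
    chrom_of: list[str] = []
    prom_se: list[tuple[int, int]] = []
    body_se: list[tuple[int, int]] = []
    for gene in genes:
        try:
            body = gene_body_window(gene, mark)
        except ShortGeneError:
            excluded.append(gene.gene_id)
            continue
        prom = promoter_window(gene, mark)
        if require_peaks is not None and not require_peaks.overlapping(
            gene.chrom, prom.start, prom.end
        ):
            excluded.append(gene.gene_id)
            continue
        ids.append(gene.gene_id)
        chrom_of.append(gene.chrom)
        prom_se.append((prom.start, prom.end))
        body_se.append((body.start, body.end))
    prom_d = np.empty(len(ids))
    body_d = np.empty(len(ids))
    chrom_arr = np.asarray(chrom_of)
    prom_arr = np.asarray(prom_se, dtype=np.int64).reshape(len(ids), 2)
    body_arr = np.asarray(body_se, dtype=np.int64).reshape(len(ids), 2)
    for chrom in np.unique(chrom_arr):
        sel = chrom_arr == chrom
        prom_d[sel] = interval_densities(
            tags, chrom, prom_arr[sel, 0], prom_arr[sel, 1]
        )
        body_d[sel] = interval_densities(
            tags, chrom, body_arr[sel, 0], body_arr[sel, 1]
        )
    table = pd.DataFrame(
        {
            "promoter_density": prom_d,
            "body_density": body_d,
            "si": body_d / np.maximum(prom_d, floor),
        },
        index=pd.Index(ids, name="gene_id"),
    )
    table.attrs["mark"] = mark.name
    table.attrs["condition"] = condition
    return table, excluded


def si_fold_change(
    control: pd.DataFrame,
    knockdown: pd.DataFrame,
    pseudocount: float = FOLD_PSEUDOCOUNT,
    floor: float = PROMOTER_FLOOR,
) -> pd.DataFrame:
    """Cross-condition SI fold change (knockdown/control) per gene.

    Uses the gene intersection of the two tables; genes whose promoter
    density is below ``floor`` in *both* conditions are excluded (no H3K4
    signal to spread).  Returns a table with si_control, si_knockdown,
    fold = (si_kd + p)/(si_ctrl + p) and its log2.
    """
    common = control.index.intersection(knockdown.index)
    if len(common) == 0:
        raise ValueError("no genes shared between conditions")
    c = control.loc[common]
    k = knockdown.loc[common]
    marked = (c["promoter_density"] >= floor) | (k["promoter_density"] >= floor)
    c, k = c[marked], k[marked]
    fold = (k["si"] + pseudocount) / (c["si"] + pseudocount)
    out = pd.DataFrame(
        {
            "si_control": c["si"],
            "si_knockdown": k["si"],
            "fold": fold,
            "log2_fold": np.log2(fold),
        }
    )
    out.attrs["n_common"] = int(len(common))
    out.attrs["n_excluded_unmarked"] = int((~marked).sum())
    return out


class ECDFResult:
    """Right-continuous empirical CDF: F(x) = #(values <= x) / n."""

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("ecdf requires at least one value")
        if not np.all(np.isfinite(values)):
            raise ValueError("ecdf values must be finite")
        self._f = _SMECDF(values, side="right")
        self.n = values.size
        self.values = np.sort(values)

    def __call__(self, x):
        return self._f(x)

    @property
    def x(self) -> np.ndarray:
        return self.values

    @property
    def y(self) -> np.ndarray:
        return np.arange(1, self.n + 1) / self.n


def ecdf(values: Sequence[float]) -> ECDFResult:
    """Empirical cumulative distribution of a sample."""
    return ECDFResult(values)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup_x |F_a(x) - F_b(x)| computed exactly over all pooled sample
    points; the two-sided p-value comes from the asymptotic Kolmogorov
    distribution evaluated at sqrt(n_eff) * D with n_eff = n_a n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_two_sample requires n >= 2 in both samples")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(fa - fb)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    return d, min(max(p, 0.0), 1.0)


@dataclass
class SlidingWindowSeries:
    """Fractions of flagged genes in sliding windows over an ordered list."""

    ordering_key: str
    window: int
    step: int
    window_centers: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.fractions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_center": self.window_centers, "fraction": self.fractions}
        )


def sliding_window_fraction(
    ordering: Mapping[str, float],
    flags: Mapping[str, bool],
    window: int = 1000,
    step: int = 1,
    ordering_key: str = "si_fold_change",
) -> SlidingWindowSeries:
    """Fraction of flagged genes per sliding window of the ordered gene list.

    Genes are sorted ascending by their ordering value (ties by gene_id);
    each window of ``window`` genes advanced by ``step`` contributes
    #flagged/window.  Genes must be present in both mappings.
    """
    ids = sorted(ordering, key=lambda g: (ordering[g], g))
    n = len(ids)
    if window > n:
        raise ValueError(f"window {window} exceeds number of genes {n}")
    if step < 1:
        raise ValueError("step must be >= 1")
    flag_arr = np.asarray([bool(flags[g]) for g in ids], dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(flag_arr)])
    starts = np.arange(0, n - window + 1, step)
    fractions = (csum[starts + window] - csum[starts]) / window
    centers = starts + (window - 1) / 2.0
    return SlidingWindowSeries(
        ordering_key=ordering_key,
        window=window,
        step=step,
        window_centers=centers,
        fractions=fractions,
    )


def classify_delta_h3k4me3(
    control_density: Mapping[str, float],
    treatment_density: Mapping[str, float],
    up_fold: float = 1.5,
    down_fold: float = 1 / 1.5,
    pseudocount: float = FOLD_PSEUDOCOUNT,
) -> pd.Series:
    """Label genes increased / no_change / decreased by promoter-density fold.

    ``increased`` iff (treat+p)/(ctrl+p) >= up_fold (boundary counts as
    increased); ``decreased`` iff the ratio is <= down_fold.
    """
    if not up_fold > 1 > down_fold:
        raise ValueError("require up_fold > 1 > down_fold")
    common = sorted(set(control_density) & set(treatment_density))
    ratios = np.asarray(
        [
            (treatment_density[g] + pseudocount) / (control_density[g] + pseudocount)
            for g in common
        ]
    )
    labels = np.where(
        ratios >= up_fold, "increased", np.where(ratios <= down_fold, "decreased", "no_change")
    )
    return pd.Series(labels, index=pd.Index(common, name="gene_id"), name="delta_class")
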