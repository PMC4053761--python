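"""Enhancer core/shore analysis around p300-proxy enhancer summits.

Each enhancer has a core (summit +- core_halfwidth) and two flanking shores
(out to shore_outer on each side).  The enhancer spreading index is shore
H3K4 density over core density; its cross-condition change is compared with
the change in core H3K27ac (the enhancer-activity readout) via two-group
ECDFs and a KS test: enhancers gaining shore methylation losing more
H3K27ac appears as a left-shifted ECDF of the high-ΔSI group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import interval_densities
from .genome_io import GeneAnnotation, PeakSet, TagCollection
from .spreading import ECDFResult, ecdf, ks_two_sample

__all__ = [
    "EnhancerGeometry",
    "enhancer_density_table",
    "enhancer_spreading_index",
    "sort_enhancers_by_signal",
    "intergenic_peaks",
    "shore_spreading_vs_acetylation",
    "ShoreAcetylationResult",
    "delta_log2",
]

CORE_HALFWIDTH = 500
SHORE_OUTER = 2000
SI_FLOOR = 0.05
AC_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class EnhancerGeometry:
    core_halfwidth: int = CORE_HALFWIDTH
    shore_outer: int = SHORE_OUTER

    def __post_init__(self) -> None:
        if not self.shore_outer > self.core_halfwidth > 0:
            raise ValueError("require shore_outer > core_halfwidth > 0")


def _summits(peaks: PeakSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    chroms = np.asarray([p.interval.chrom for p in peaks])
    pos = np.asarray([p.summit_position for p in peaks], dtype=np.int64)
    ids = [f"{peaks.name}_{i}" for i in range(len(peaks))]
    return chroms, pos, ids


def enhancer_density_table(
    tags: TagCollection,
    enhancers: PeakSet,
    geometry: EnhancerGeometry = EnhancerGeometry(),
) -> pd.DataFrame:
    """Per-enhancer core and shore RPBM densities for one mark/sample.

    Shore density pools both flanks (total overlap bp over total shore
    length).  Indexed by enhancer id (peak-set name + ordinal).
    """
    chroms, pos, ids = _summits(enhancers)
    chw, outer = geometry.core_halfwidth, geometry.shore_outer
    core = np.empty(len(ids))
    shore = np.empty(len(ids))
    scale = tags.library_size / 1e6
    shore_len = 2 * (outer - chw)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        p = pos[sel]
        core[sel] = interval_densities(
            tags, chrom, np.maximum(p - chw, 0), p + chw
        )
        left = tags.overlap_bp(chrom, np.maximum(p - outer, 0), np.maximum(p - chw, 0))
        right = tags.overlap_bp(chrom, p + chw, p + outer)
        shore[sel] = (left + right) / shore_len / scale
    return pd.DataFrame(
        {"core_density": core, "shore_density": shore},
        index=pd.Index(ids, name="enhancer_id"),
    )


def enhancer_spreading_index(
    densities: pd.DataFrame, floor: float = SI_FLOOR
) -> pd.Series:
    """Shore density / max(core density, floor) per enhancer."""
    si = densities["shore_density"] / np.maximum(densities["core_density"], floor)
    si.name = "si"
    return si


def sort_enhancers_by_signal(
    enhancers: PeakSet,
    signal: TagCollection,
    geometry: EnhancerGeometry = EnhancerGeometry(),
    k: int = 4,
) -> tuple[list[str], list[list[str]]]:
    """Order enhancers by descending core signal density; split into k groups.

    Returns (ordered ids, k equal-size groups with the remainder in the last
    group); group 0 is the top (e.g. top-25% H3K27ac when k=4).  Ties break
    by enhancer id.
    """
    if len(enhancers) < k:
        raise ValueError(f"need at least {k} enhancers for {k} groups")
    dens = enhancer_density_table(signal, enhancers, geometry)["core_density"]
    ordered = sorted(dens.index, key=lambda e: (-dens[e], e))
    n = len(ordered)
    size = n // k
    groups = [ordered[i * size:(i + 1) * size] for i in range(k - 1)]
    groups.append(ordered[(k - 1) * size:])
    return ordered, groups


def intergenic_peaks(
    peaks: PeakSet, genes: GeneAnnotation, margin: int = 2000
) -> PeakSet:
    """Peaks that do not overlap any gene extended by ``margin`` bp."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        iv = gene.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            max(iv.start - margin, 0), iv.end + margin
        )
    kept = [
        p
        for p in peaks
        if not (
            p.interval.chrom in trees
            and trees[p.interval.chrom].overlap(p.interval.start, p.interval.end)
        )
    ]
    return PeakSet(f"{peaks.name}_intergenic", kept)


@dataclass
class ShoreAcetylationResult:
    """Two-group ΔH3K27ac ECDF comparison, split at the median ΔSI."""

    low_group: list[str]
    high_group: list[str]
    ecdf_low: ECDFResult
    ecdf_high: ECDFResult
    ks_d: float
    ks_p: float


def shore_spreading_vs_acetylation(
    delta_si: pd.Series,
    delta_ac: pd.Series,
    n_groups: int = 2,
) -> ShoreAcetylationResult:
    """Compare ΔH3K27ac distributions between low- and high-ΔSI enhancers.

    Enhancers are split at the median ΔSI (ties by id); each group's ECDF of
    ΔH3K27ac is returned together with the two-sample KS test between them.
    """
    if n_groups != 2:
        raise ValueError("only the two-group median split is supported")
    common = sorted(set(delta_si.index) & set(delta_ac.index))
    if len(common) < 4:
        raise ValueError("need at least 2 enhancers per group")
    ordered = sorted(common, key=lambda e: (delta_si[e], e))
    half = len(ordered) // 2
    low, high = ordered[:half], ordered[half:]
    ac_low = delta_ac[low].to_numpy(float)
    ac_high = delta_ac[high].to_numpy(float)
    d, p = ks_two_sample(ac_low, ac_high)
    return ShoreAcetylationResult(
        low_group=low,
        high_group=high,
        ecdf_low=ecdf(ac_low),
        ecdf_high=ecdf(ac_high),
        ks_d=d,
        ks_p=p,
    )


def delta_log2(
    control: pd.Series, knockdown: pd.Series, pseudocount: float = AC_PSEUDOCOUNT
) -> pd.Series:
    """log2((knockdown + p)/(control + p)) on the shared index."""
    common = control.index.intersection(knockdown.index)
    out = np.log2(
        (knockdown.loc[common] + pseudocount) / (control.loc[common] + pseudocount)
    )
    out.name = "delta_log2"
    return out
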