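"""End-to-end pipeline: simulate -> densities -> SI -> KS -> sliding windows
-> enhancer analysis -> co-occupancy -> machine-readable summary.

Given one :class:`RunConfig` the pipeline either generates a synthetic
dataset or reads user files, runs every analysis stage, writes one TSV per
stage plus ``summary.json``, and is deterministic: re-running with the same
config and seed reproduces byte-identical numeric outputs (timestamps go to
the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats

from . import __version__
from .cooccupancy import (
    correlate_and_cluster,
    promoter_density_matrix,
    promoter_occupancy,
    venn_counts,
)
from .coverage import simple_enrichment_caller
from .enhancers import (
    EnhancerGeometry,
    delta_log2,
    enhancer_density_table,
    enhancer_spreading_index,
    shore_spreading_vs_acetylation,
)
from .expression import call_de, read_counts_tsv
from .genome_io import (
    MarkKind,
    read_gene_annotation,
    read_peaks_bed,
    read_tags_bed,
)
from .spreading import (
    classify_delta_h3k4me3,
    ks_two_sample,
    si_fold_change,
    sliding_window_fraction,
    spreading_table,
)
from .synthetic import H3K4_MARKS, SimulationParams, SyntheticDataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SampleSpec:
    sample_id: str
    mark: str
    condition: str
    path: str


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    outdir: str
    seed: int = 0
    # synthetic mode: parameter overrides for SimulationParams (seed is set
    # from this config); None -> file mode.
    simulate: dict[str, Any] | None = field(default_factory=dict)
    # file mode inputs
    samples: list[SampleSpec] = field(default_factory=list)
    annotation_path: str | None = None
    annotation_dialect: str = "BED12"
    counts_path: str | None = None
    enhancer_peaks_path: str | None = None
    # comparisons: (control, treatment) condition labels
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    # thresholds and windows
    fold_threshold: float = 1.5
    fdr_threshold: float = 0.001
    min_rpkm: float = 1.0
    de_dispersion: float | None = None  # None: generator's value in synthetic mode
    de_window: int = 1000
    bivalent_window: int = 500
    marks: tuple[str, ...] = H3K4_MARKS
    core_halfwidth: int = 500
    shore_outer: int = 2000
    write_tag_beds: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        comparisons = [tuple(c) for c in raw.pop("comparisons", [])]
        marks = tuple(raw.pop("marks", H3K4_MARKS))
        return cls(samples=samples, comparisons=comparisons, marks=marks, **raw)

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                s.path for s in self.samples if not Path(s.path).exists()
            ]
            for p in (self.annotation_path, self.counts_path,
                      self.enhancer_peaks_path):
                if p is not None and not Path(p).exists():
                    missing.append(p)
            if self.annotation_path is None:
                raise PipelineError("validate", "file mode requires annotation_path")
            if missing:
                raise PipelineError(
                    "validate", f"missing input files: {', '.join(missing)}"
                )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage; write stage TSVs + summary.json; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("h3k4spread.pipeline")
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    log.setLevel(logging.INFO)
    file_handler = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(file_handler)
    try:
        return _run_pipeline_logged(config, outdir, log)
    finally:
        log.removeHandler(file_handler)
        file_handler.close()


def _run_pipeline_logged(
    config: RunConfig, outdir: Path, log: logging.Logger
) -> dict[str, Any]:
    log.info("h3k4spread %s pipeline start (seed=%d)", __version__, config.seed)
    config.validate()

    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "mode": "synthetic" if config.simulate is not None else "files",
        "marks": {},
        "sliding_window_de": {},
        "enhancers": {},
    }

    # ------------------------------------------------------------------
    # stage: inputs (simulate or load)
    # ------------------------------------------------------------------
    dataset: SyntheticDataset | None = None
    if config.simulate is not None:
        params = SimulationParams(seed=config.seed, **config.simulate)
        dataset = SyntheticDataset.generate(params)
        dataset.write(outdir / "inputs")
        annotation = dataset.annotation
        enhancer_peaks = dataset.enhancers
        conditions = list(params.conditions)
        comparisons = config.comparisons or [
            (params.conditions[0], params.conditions[-1])
        ]
        gene_tags = {
            (cond, mark): dataset.chip_tags(cond, mark)
            for cond in conditions
            for mark in config.marks
        }
        if config.write_tag_beds:
            for (cond, mark), tags in gene_tags.items():
                tags.write_bed(outdir / "inputs" / f"{mark}_{cond}.bed")
        expression = dataset.expression_table()
        expression.write_tsv(outdir / "inputs" / "counts.tsv")
        dispersion = (
            params.nb_dispersion
            if config.de_dispersion is None
            else config.de_dispersion
        )
        log.info("simulated %d genes, %d enhancers", len(annotation),
                 len(enhancer_peaks))
    else:
        try:
            annotation = read_gene_annotation(
                config.annotation_path, config.annotation_dialect
            )
        except ValueError as exc:
            raise PipelineError("inputs", str(exc)) from exc
        gene_tags = {}
        conditions = []
        for s in config.samples:
            gene_tags[(s.condition, s.mark)] = read_tags_bed(
                s.path, sample_id=s.sample_id
            )
            if s.condition not in conditions:
                conditions.append(s.condition)
        comparisons = config.comparisons or (
            [(conditions[0], conditions[-1])] if len(conditions) >= 2 else []
        )
        expression = (
            read_counts_tsv(config.counts_path) if config.counts_path else None
        )
        enhancer_peaks = (
            read_peaks_bed(config.enhancer_peaks_path, "p300")
            if config.enhancer_peaks_path
            else None
        )
        dispersion = config.de_dispersion or 0.0
    summary["n_genes"] = len(annotation)

    # ------------------------------------------------------------------
    # stage: spreading index + KS per mark
    # ------------------------------------------------------------------
    si_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for (cond, mark), tags in gene_tags.items():
        mk = MarkKind.from_name(mark)
        table, excluded = spreading_table(tags, annotation, mk, condition=cond)
        table.to_csv(outdir / f"spreading_{mark}_{cond}.tsv", sep="\t")
        si_tables[(cond, mark)] = table
        log.info("SI %s/%s: %d genes (%d excluded short)", mark, cond,
                 len(table), len(excluded))

    fold_tables: dict[str, pd.DataFrame] = {}
    for ctrl, treat in comparisons:
        for mark in config.marks:
            if (ctrl, mark) not in si_tables or (treat, mark) not in si_tables:
                continue
            fold = si_fold_change(si_tables[(ctrl, mark)], si_tables[(treat, mark)])
            fold.to_csv(outdir / f"si_fold_{mark}_{treat}_vs_{ctrl}.tsv", sep="\t")
            fold_tables[mark] = fold
            d, p = ks_two_sample(
                fold["si_control"].to_numpy(), fold["si_knockdown"].to_numpy()
            )
            summary["marks"][mark] = {
                "comparison": [ctrl, treat],
                "n_genes": int(len(fold)),
                "ks_d": d,
                "ks_p": p,
            }
            log.info("KS %s: D=%.4f p=%.3g (n=%d)", mark, d, p, len(fold))

    # ------------------------------------------------------------------
    # stage: differential expression
    # ------------------------------------------------------------------
    de_results = None
    if expression is not None and comparisons:
        ctrl, treat = comparisons[0]
        try:
            de_results = call_de(
                expression.counts[[ctrl]],
                expression.counts[[treat]],
                expression.exon_lengths,
                fold_threshold=config.fold_threshold,
                fdr_threshold=config.fdr_threshold,
                min_rpkm=config.min_rpkm,
                dispersion=dispersion,
            )
        except KeyError as exc:
            raise PipelineError("de", f"counts table lacks condition {exc}") from exc
        de_results.to_csv(outdir / "de_results.tsv", sep="\t")
        summary["de"] = {
            "comparison": [ctrl, treat],
            "n_genes": int(len(de_results)),
            "n_de": int(de_results["is_de"].sum()),
            "fold_threshold": config.fold_threshold,
            "fdr_threshold": config.fdr_threshold,
            "min_rpkm": config.min_rpkm,
        }
        log.info("DE: %d/%d genes", summary["de"]["n_de"], len(de_results))

    # ------------------------------------------------------------------
    # stage: sliding-window %DE over SI-fold-change rank
    # ------------------------------------------------------------------
    if de_results is not None:
        for mark, fold in fold_tables.items():
            common = fold.index.intersection(de_results.index)
            window = min(config.de_window, len(common))
            series = sliding_window_fraction(
                fold.loc[common, "log2_fold"].to_dict(),
                de_results.loc[common, "is_de"].to_dict(),
                window=window,
                step=1,
                ordering_key=f"si_log2_fold_{mark}",
            )
            series.to_frame().to_csv(
                outdir / f"sliding_de_{mark}.tsv", sep="\t", index=False
            )
            rho = _scipy_stats.spearmanr(
                np.arange(len(series)), series.fractions
            ).statistic if len(series) > 2 else float("nan")
            summary["sliding_window_de"][mark] = {
                "window": window,
                "n_windows": len(series),
                "spearman_rho": float(rho),
                "fraction_first": float(series.fractions[0]),
                "fraction_last": float(series.fractions[-1]),
            }

    # ------------------------------------------------------------------
    # stage: delta-H3K4me3 promoter classification
    # ------------------------------------------------------------------
    ctrl, treat = comparisons[0] if comparisons else (None, None)
    if ctrl is not None and ("H3K4me3" in config.marks):
        key_c, key_t = (ctrl, "H3K4me3"), (treat, "H3K4me3")
        if key_c in si_tables and key_t in si_tables:
            labels = classify_delta_h3k4me3(
                si_tables[key_c]["promoter_density"].to_dict(),
                si_tables[key_t]["promoter_density"].to_dict(),
                up_fold=config.fold_threshold,
                down_fold=1 / config.fold_threshold,
            )
            labels.to_frame().to_csv(outdir / "delta_h3k4me3_classes.tsv", sep="\t")
            summary["delta_h3k4me3_classes"] = (
                labels.value_counts().sort_index().to_dict()
            )

    # ------------------------------------------------------------------
    # stage: enhancer shore analysis
    # ------------------------------------------------------------------
    if dataset is not None and enhancer_peaks is not None:
        geometry = EnhancerGeometry(config.core_halfwidth, config.shore_outer)
        ctrl, treat = comparisons[0]
        ac_ctrl = enhancer_density_table(
            dataset.enhancer_tags(ctrl, "H3K27ac"), enhancer_peaks, geometry
        )["core_density"]
        ac_treat = enhancer_density_table(
            dataset.enhancer_tags(treat, "H3K27ac"), enhancer_peaks, geometry
        )["core_density"]
        d_ac = delta_log2(ac_ctrl, ac_treat)
        for mark in config.marks:
            dens_c = enhancer_density_table(
                dataset.enhancer_tags(ctrl, mark), enhancer_peaks, geometry
            )
            dens_t = enhancer_density_table(
                dataset.enhancer_tags(treat, mark), enhancer_peaks, geometry
            )
            d_si = enhancer_spreading_index(dens_t) - enhancer_spreading_index(
                dens_c
            )
            res = shore_spreading_vs_acetylation(d_si, d_ac)
            table = pd.DataFrame(
                {
                    "delta_si": d_si,
                    "delta_h3k27ac": d_ac,
                    "group": [
                        "high" if e in set(res.high_group) else "low"
                        for e in d_si.index
                    ],
                }
            )
            table.to_csv(outdir / f"enhancer_shift_{mark}.tsv", sep="\t")
            summary["enhancers"][mark] = {
                "n_enhancers": int(len(d_si)),
                "ks_d": res.ks_d,
                "ks_p": res.ks_p,
                "median_delta_ac_low": float(np.median(res.ecdf_low.values)),
                "median_delta_ac_high": float(np.median(res.ecdf_high.values)),
            }
            log.info("enhancer %s: KS p=%.3g", mark, res.ks_p)

    # ------------------------------------------------------------------
    # stage: co-occupancy and sample correlation
    # ------------------------------------------------------------------
    if len(gene_tags) >= 2:
        matrix = promoter_density_matrix(list(gene_tags.values()), annotation)
        corr, leaf_order, newick = correlate_and_cluster(matrix)
        corr.to_csv(outdir / "promoter_correlation.tsv", sep="\t")
        (outdir / "promoter_dendrogram.nwk").write_text(newick + "\n")
        summary["correlation_leaf_order"] = leaf_order
    if dataset is not None and "H3K4me3" in config.marks:
        inp = dataset.input_tags()
        occ = {}
        for cond in conditions:
            peaks = simple_enrichment_caller(
                gene_tags[(cond, "H3K4me3")], inp, name=f"H3K4me3_{cond}"
            )
            occ[cond] = promoter_occupancy(peaks, annotation)
        if len(occ) >= 2:
            venn = venn_counts({c: v.to_numpy() for c, v in occ.items()})
            summary["h3k4me3_promoter_venn"] = venn
            pd.DataFrame(occ).to_csv(outdir / "promoter_occupancy.tsv", sep="\t")

    # ------------------------------------------------------------------
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    log.info("wrote %s", summary_path)
    return summary
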