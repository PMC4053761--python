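# h3k4spread

Quantitative analysis of **H3K4-methylation spreading** from ChIP-seq data.

Active promoters carry sharp H3K4me3/me2 peaks focused at the transcription
start site; H3K4 demethylases (KDM5B, LSD1) keep these marks from diffusing
into transcribed regions and enhancer flanks.  When such a demethylase is
depleted, methylation *spreads* from promoters into gene bodies and from
enhancer cores into their shores, with consequences for gene expression and
enhancer activity.  `h3k4spread` implements the statistics used to detect
and interpret this redistribution, for epigenomics analysts working with
aligned ChIP-seq tags and gene-level RNA-seq counts.

## The spreading index

For a gene *g* and mark *m*, define a promoter bin `P` as a symmetric window
around the TSS (1 kb for H3K4me3, 1.5 kb for H3K4me2, 3 kb for H3K4me1) and
the gene body `B` as the region from the promoter bin's downstream edge to
the TES.  With tag densities in RPBM (reads per base pair per million mapped
reads),

```
SI(g, m) = density_B(g, m) / max(density_P(g, m), eps)        eps = 0.05 RPBM
```

An SI increase between conditions means methylation moved from the promoter
into the transcribed region.  The package compares per-gene SI distributions
between conditions with ECDFs and the two-sample Kolmogorov–Smirnov test
(D computed exactly over pooled points; asymptotic p with effective
n = n₁n₂/(n₁+n₂)), and links SI fold changes to differential expression via
sliding-window %DE curves over SI-fold-ranked genes.  The same core/shore
logic applies to enhancers (p300-proxy summits, ±0.5 kb core, shores out to
±2 kb), where shore spreading is compared against the change in core
H3K27ac, the enhancer-activity readout.

Modules:

| module        | contents |
|---------------|----------|
| `genome_io`   | interval/gene/tag/peak data model, BED/BED12/GTF readers, promoter & gene-body windows |
| `coverage`    | binned density tracks, RPBM normalization, input-normalized log2 tracks, exact interval densities, a minimal island caller |
| `profiles`    | TSS-anchored and length-scaled TSS→TES metagene profiles, expression stratification, fold-change curves |
| `spreading`   | spreading index, SI fold change, ECDF, KS test, sliding-window fractions, ΔH3K4me3 classification |
| `cooccupancy` | promoter occupancy, Venn counts, bivalent-gene calls, sample–sample promoter-density correlation with clustering |
| `expression`  | RPKM, conditional-test DE calling (fold > 1.5, FDR < 0.001, RPKM floor), precomputed-table import |
| `enhancers`   | enhancer core/shore densities, enhancer SI, H3K27ac sorting, ΔSI vs ΔH3K27ac ECDF comparison |
| `synthetic`   | seeded generator for genome, ChIP tags, enhancer signal, and NB counts, with ground truth |
| `pipeline`/`cli` | end-to-end orchestration (`h3k4spread run-all`) and per-stage subcommands |

## Worked example

Generate the default synthetic experiment (2,000 genes on 2×25 Mb
chromosomes, 2×10⁶ tags per sample, gene-body spread fraction 0.1 in
control vs 0.4 after knockdown) and test for an SI shift:

```python
from h3k4spread import SimulationParams, SyntheticDataset, MarkKind
from h3k4spread.spreading import spreading_table, si_fold_change, ks_two_sample

params = SimulationParams(seed=1)
ds = SyntheticDataset.generate(params)
mark = MarkKind.from_name("H3K4me3")
si = {}
for cond in ("control", "knockdown"):
    tags = ds.chip_tags(cond, "H3K4me3")
    si[cond], _ = spreading_table(tags, ds.annotation, mark, condition=cond)
fold = si_fold_change(si["control"], si["knockdown"])
d, p = ks_two_sample(fold["si_control"], fold["si_knockdown"])
```

This prints:

```
n genes analysed: 2000
median SI control:   0.035
median SI knockdown: 0.117
KS D = 0.661, p = 0
            si_control  si_knockdown    fold  log2_fold
gene_id
gene_00000       0.022         0.081   1.808      0.855
gene_00001       0.036         1.331  15.968      3.997
gene_00002       0.024         0.075   1.679      0.748
```

The knockdown tripled the typical gene's body-to-promoter density ratio
(median SI 0.035 → 0.117): H3K4me3 has spread into gene bodies.  The SI
ECDF is right-shifted and the KS p-value underflows to 0 (far below 1e-5),
so the shift is systematic, not a property of a few genes.  Per-gene fold
columns feed the sliding-window %DE analysis
(`h3k4spread.spreading.sliding_window_fraction`).

The same run from the shell:

```sh
h3k4spread run-all --seed 1 --outdir run1
```

writes per-stage TSVs (spreading tables, SI fold changes, DE results,
sliding-window series, enhancer ΔSI/ΔH3K27ac tables, promoter correlation
matrix) plus a machine-readable `summary.json`.  Re-running with the same
seed reproduces the outputs byte-for-byte.

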