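# Methods

## Coordinates, tags, and densities

All coordinates are 0-based, half-open `[start, end)`.  BED input is used
natively; GTF is converted on read.  A ChIP tag is a strand-aware 5' read
position; before any counting it is extended 150 bp (configurable) in its
strand direction, a conventional proxy for the sequenced fragment — the
source studies do not state a fragment length.  Tags whose extension would
run past the chromosome start are shifted to begin at 0, so every fragment
keeps the same length and coverage totals are exactly conserved.

Densities are reported in RPBM: mean per-bp fragment coverage divided by
(library size / 10⁶).  Spreading-index and profile computations use exact
fragment/interval overlap counts (prefix sums over sorted fragment starts),
never a binned track, so bin-edge artifacts cannot enter the core
statistic.  Binned `DensityTrack`s (default 50 bp) exist for browser-style
output and input-normalized log2 ratio tracks, which use an additive
pseudocount of 0.1 RPBM.

## Promoter and gene-body windows

The promoter bin is a symmetric window around the TSS: half-width 500 bp
for H3K4me3, 750 bp for H3K4me2, 1,500 bp for H3K4me1 (per the mark's
typical breadth); other marks default to ±2 kb.  The gene body runs from
the promoter bin's downstream edge to the TES.  The two windows are
disjoint, contiguous, and their union ends at the TES; both transform
exactly under coordinate reflection + strand flip (property-tested).  Genes
whose body window would be empty are flagged "short" and excluded from SI
analyses, with the exclusion list reported.

## The spreading index and its comparisons

`SI = body density / max(promoter density, ε)` with ε = 0.05 RPBM; the
floor prevents division blow-ups at unmarked promoters.  SI is exactly
invariant to library duplication (numerator and denominator share the
library).  Cross-condition fold change is `(SI_kd + ε′)/(SI_ctrl + ε′)`
with ε′ = 0.05; genes whose promoter density is below ε in *both*
conditions carry no mark to spread and are excluded (count reported).  An
optional peak-set filter restricts the analysis to genes whose promoter
overlaps a called region of the mark.

Distribution shifts use the two-sample KS test: D is the exact supremum of
|F₁ − F₂| over all pooled sample points; the two-sided p-value is the
asymptotic Kolmogorov survival function at √(n_eff)·D with
n_eff = n₁n₂/(n₁+n₂).  The asymptotic form is appropriate here because the
analyses operate on thousands of genes; it is anti-conservative below a few
dozen observations.

Coupling between spreading and expression (or bivalency) is summarised by
sliding-window fractions: genes sorted ascending by SI log-fold (ties by
id), window of 1,000 genes for %DE (500 for %bivalent), step 1.  Note the
series has only ≈ n/window statistically independent points; trend
statistics computed on it must account for the strong window overlap
autocorrelation (the package reports the series itself plus a Spearman ρ
against window index as a descriptive summary).

Promoter ΔH3K4me3 classification uses pseudocounted density ratios with
symmetric 1.5-fold thresholds (boundary counts as changed); the thresholds
are configurable and were chosen to match the DE fold threshold.

## Enhancers

Enhancers are p300-proxy summits with a ±500 bp core and shores from the
core edge out to ±2 kb (geometry configurable; the source analyses do not
state one).  The enhancer SI is shore density over floored core density.
Activity change is log2 core H3K27ac ratio (pseudocount 0.1 RPBM),
measured on the core only, since H3K27ac marks the active element itself.
Enhancers are split at the median ΔSI into low/high groups and the two
ΔH3K27ac ECDFs are compared by KS; a left-shifted high-ΔSI group means
shore spreading accompanies activity loss.  Intergenic filtering removes
peaks overlapping any gene ±2 kb.

## Differential expression

RPKM = 10⁹·count/(library·exon length).  The built-in caller is a
conditional test of the treatment count against the library-size-ratio
expectation on the pooled per-gene count, two-sided by minimum likelihood,
BH-corrected; all-zero genes get p = 1 and are excluded from the BH
denominator.  With `dispersion = 0` the conditional distribution is exactly
binomial — correct for Poisson-distributed counts.  Real counts are
overdispersed, and a binomial conditional test is then anti-conservative
(variance inflation ≈ 1 + 2φμp q); the caller therefore accepts a plug-in
NB dispersion φ and substitutes a moment-matched beta-binomial
(ρ ≈ 2φp q), which restores null calibration (verified: ≤ 0.5% of genes
reach FDR < 0.001 in a 5,000-gene null NB simulation).  This is a
deliberately simple stand-in, not a replacement for a dedicated DE package:
it has no per-gene dispersion estimation and no replicate-level modelling,
and the canonical path for real data is importing a precomputed DE table
(`de_from_table`).  A gene is DE when |fold| > 1.5, FDR < 0.001, and the
larger group-mean RPKM exceeds 1 (all configurable; an alternative RPKM
floor of 11 appears in some published analyses and can be set the same
way).

## Co-occupancy and sample similarity

Promoter occupancy is ≥1 bp overlap between a peak and the ±2 kb TSS
window (half-open).  Venn regions are exclusive and sum to the universe.
Bivalent genes are the AND of H3K4me3 and H3K27me3 promoter occupancy.
Sample similarity is Pearson correlation of log2(density + 0.1) promoter
vectors with average-linkage clustering on 1 − r.  This is a structural
substitute for self-organizing-map affinity matrices used in some published
work: it yields a comparable clustered similarity matrix but is not
numerically comparable to such affinities.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at a
scale a single CPU handles in seconds:

* **Genome** — 2 chromosomes × 25 Mb; 2,000 genes with lognormal lengths
  (median 10 kb, σ = 0.5, clipped to 2–80 kb), placed with ≥10 kb gaps plus
  exponential jitter (mean 2 kb); 1,000 enhancer summits placed
  intergenically, ≥4 kb from genes and from each other.  The chromosome
  length is chosen so that the gene count, length distribution, and minimum
  gap are jointly feasible with slack.
* **Gene ChIP** — 2×10⁶ tags per sample: uniform background (0.01 tags/bp
  of genome ≈ 25% of the library) plus per-gene signal mass proportional to
  expression rank.  A fraction s_g of each gene's mass is uniform over its
  body; the rest is Gaussian at the TSS (sd = half the mark's promoter
  half-width).  s_g = condition spread fraction × a per-gene lognormal
  multiplier (σ = 0.35), clipped to 1.  Condition spread fractions default
  to 0.1 (control) vs 0.4 (knockdown) — the study condition all shift
  analyses are run under.
* **Enhancer ChIP** — 10⁶ tags per sample; core Gaussian (sd 250 bp) +
  uniform shore mixture with per-enhancer shore fractions built like s_g.
  H3K27ac is core-only; its per-enhancer mass is scaled by
  exp(γ·Δshore fraction) with γ = −3, so enhancers whose shores spread most
  lose the most acetylation *relative to their peers* (the multinomial
  library normalization absorbs any global shift — as real library-size
  normalization would).
* **Expression** — NB counts (dispersion 0.01, i.e. BCV 0.1, typical of
  clonal cell-line comparisons), library 3×10⁶, lognormal baseline (σ = 1).
  Each gene is DE with probability logistic(α + β·r), r the normalized rank
  of its true Δspread, α = −2.2 (≈10% baseline), β = 3 (≈10%→69% across the
  rank range); DE genes get log2FC of ±Uniform(0.6, 2).

All randomness flows from one master seed through named child streams
(`default_rng([seed, stream...])`), so identical parameters give
byte-identical outputs, and every emitted library has exactly the declared
tag count.  Ground truth (per-gene spread fractions, DE flags, effect
sizes; per-enhancer shore fractions and acetylation scalings) is emitted
for parameter-recovery tests.

What the generator does *not* emulate: nucleosome positioning, mappability
and GC structure, duplicate reads, peak-shape asymmetries, replicate-level
biological variability of ChIP efficiency, or any H3K27me3/bivalency
channel.  Passing tests therefore demonstrate that the statistics recover
the injected structure under idealized sampling noise — not that they are
robust to every artifact of real sequencing data.

## Numerical and design choices

* Exact overlap counting uses integer arithmetic until the final division,
  so the SI is reproducible to the last bit and matches a per-bp
  brute-force implementation float-for-float.
* The island caller is plumbing for synthetic pipelines: count-ratio
  threshold plus a Poisson upper-tail filter (p < 10⁻⁵) against the scaled
  control expectation floored at the chromosome mean.  It mimics the
  *shape* of gap-merged islands only and makes no FDR claim.
* Expression stratification sorts descending with remainder-to-last-group
  and lexicographic tie-breaks; all orderings in the package are
  deterministic under ties.
* Profiles weight genes equally (not by tag count); minus-strand rows are
  reversed so downstream is always rightward.
* `summary.json` contains no timestamps or versions, so same-seed runs are
  byte-identical; wall-clock and version information goes to the log.

## Known limitations

* The KS p-value is asymptotic only; do not trust it below ~30 points per
  group.
* The DE stand-in pools replicates and cannot borrow dispersion strength
  across genes.
* Sliding-window trend summaries are descriptive; their null distribution
  is dominated by window-overlap autocorrelation (≈ n/window independent
  points), so a formal flatness test must use block-level statistics.
* BED parsing assumes well-formed single-chromosome-sorted-ish input files
  of moderate size (whole files are read into memory); BAM input is out of
  scope.
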