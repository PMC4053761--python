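"""Generator: determinism, conservation, geometry, limits, truth recovery."""

import numpy as np
import pytest
from scipy import stats

from h3k4spread.genome_io import MarkKind
from h3k4spread.spreading import sliding_window_fraction, spreading_table
from h3k4spread.synthetic import SimulationParams, SyntheticDataset

SMALL = dict(
    n_chromosomes=2,
    chromosome_length=4_000_000,
    n_genes=150,
    n_enhancers=60,
    library_size=100_000,
    enhancer_library_size=60_000,
    counts_library_size=300_000,
    background_rate=0.002,
)


def small_params(seed=0, **kw):
    merged = {**SMALL, **kw}
    return SimulationParams(seed=seed, **merged)


class TestGenome:
    def test_gene_placement_disjoint_with_gaps(self):
        ds = SyntheticDataset.generate(small_params())
        p = ds.params
        assert len(ds.annotation) == p.n_genes
        for chrom in ds.annotation.chromosomes:
            genes = ds.annotation.on_chromosome(chrom)
            for g1, g2 in zip(genes, genes[1:]):
                assert g2.interval.start - g1.interval.end >= p.min_gene_gap
            assert genes[-1].interval.end <= p.chromosome_length

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="chromosome_length"):
            SyntheticDataset.generate(
                small_params(n_genes=2000, chromosome_length=2_000_000)
            )

    def test_enhancers_intergenic(self):
        ds = SyntheticDataset.generate(small_params())
        margin = ds.params.enhancer_margin
        for peak in ds.enhancers:
            chrom = peak.interval.chrom
            s = peak.summit_position
            for g in ds.annotation.on_chromosome(chrom):
                assert not (
                    g.interval.start - margin < s < g.interval.end + margin
                )

    def test_same_seed_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            ds = SyntheticDataset.generate(small_params(seed=42))
            out = tmp_path / run
            ds.write(out)
            ds.chip_tags("control", "H3K4me3").write_bed(out / "tags.bed")
            ds.expression_table().write_tsv(out / "counts.tsv")
        for name in ("genes.bed12", "enhancers.bed", "gene_truth.tsv",
                     "tags.bed", "counts.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = SyntheticDataset.generate(small_params(seed=1))
        b = SyntheticDataset.generate(small_params(seed=2))
        assert not np.array_equal(
            a.chip_tags("control", "H3K4me3").tags["chr1"][0],
            b.chip_tags("control", "H3K4me3").tags["chr1"][0],
        )


class TestChip:
    def test_tag_counts_equal_library_size(self):
        ds = SyntheticDataset.generate(small_params())
        for cond in ("control", "knockdown"):
            tags = ds.chip_tags(cond, "H3K4me2")
            assert tags.n_tags == ds.params.library_size
            assert tags.library_size == ds.params.library_size
        etags = ds.enhancer_tags("control", "H3K27ac")
        assert etags.n_tags == ds.params.enhancer_library_size

    def test_no_spreading_limit_keeps_bodies_near_background(self):
        params = small_params(spread_fraction=(0.0, 0.0))
        ds = SyntheticDataset.generate(params)
        tags = ds.chip_tags("control", "H3K4me3")
        table, _ = spreading_table(
            tags, ds.annotation, MarkKind.from_name("H3K4me3")
        )
        # genes with real promoter signal have essentially empty bodies
        marked = table[table["promoter_density"] > 1.0]
        background_rpbm = (
            ds.params.background_rate
            * ds.params.fragment_extension
            / (ds.params.library_size / 1e6)
        )
        assert marked["body_density"].median() <= 3 * background_rpbm
        assert marked["si"].median() < 0.1

    def test_full_spreading_limit_empties_promoters(self):
        params = small_params(spread_fraction=(1.0, 1.0),
                              spread_multiplier_sigma=0.0)
        ds = SyntheticDataset.generate(params)
        tags = ds.chip_tags("control", "H3K4me3")
        table, _ = spreading_table(
            tags, ds.annotation, MarkKind.from_name("H3K4me3")
        )
        strong = table[table["body_density"] > 2.0]
        assert (strong["si"] > 1.0).mean() > 0.9

    def test_h3k27ac_decoupled_when_gamma_zero(self):
        from h3k4spread.enhancers import enhancer_density_table

        params = small_params(h3k27ac_coupling=0.0)
        ds = SyntheticDataset.generate(params)
        ac_c = enhancer_density_table(
            ds.enhancer_tags("control", "H3K27ac"), ds.enhancers
        )["core_density"]
        ac_k = enhancer_density_table(
            ds.enhancer_tags("knockdown", "H3K27ac"), ds.enhancers
        )["core_density"]
        d_ac = np.log2((ac_k + 0.1) / (ac_c + 0.1))
        rho = stats.spearmanr(ds.enhancer_truth["delta_shore"], d_ac).statistic
        assert abs(rho) < 0.15

    def test_h3k27ac_suppressed_when_gamma_negative(self):
        from h3k4spread.enhancers import enhancer_density_table

        ds = SyntheticDataset.generate(small_params())  # gamma = -3
        ac_c = enhancer_density_table(
            ds.enhancer_tags("control", "H3K27ac"), ds.enhancers
        )["core_density"]
        ac_k = enhancer_density_table(
            ds.enhancer_tags("knockdown", "H3K27ac"), ds.enhancers
        )["core_density"]
        d_ac = np.log2((ac_k + 0.1) / (ac_c + 0.1))
        # coupling acts on relative enhancer mass: enhancers whose shores
        # spread more lose more acetylation than their peers
        rho = stats.spearmanr(ds.enhancer_truth["delta_shore"], d_ac).statistic
        assert rho < -0.5


class TestCounts:
    def test_beta_zero_gives_flat_de_rate(self):
        """Under de_beta=0 the DE rate must not trend with the spreading
        change: first-half vs last-half rate difference within binomial
        noise (5 sigma) for every seed."""
        for seed in range(5):
            params = small_params(seed=seed, n_genes=400,
                                  chromosome_length=8_000_000, de_beta=0.0)
            ds = SyntheticDataset.generate(params)
            truth = ds.gene_truth.sort_values("delta_spread")
            flags = truth["is_de"].to_numpy()
            half = len(flags) // 2
            diff = abs(flags[:half].mean() - flags[half:].mean())
            q = flags.mean()
            sigma = np.sqrt(2 * q * (1 - q) / half) if q > 0 else 1.0
            assert diff <= 5 * sigma

    def test_beta_positive_gives_monotone_de_rate(self):
        params = small_params(n_genes=2000, chromosome_length=25_000_000)
        ds = SyntheticDataset.generate(params)
        truth = ds.gene_truth
        series = sliding_window_fraction(
            truth["delta_spread"].to_dict(),
            truth["is_de"].to_dict(),
            window=200,
            step=1,
        )
        rho = stats.spearmanr(
            np.arange(len(series)), series.fractions
        ).statistic
        assert rho > 0.8

    def test_dispersion_zero_is_poisson_like(self):
        params = small_params(nb_dispersion=0.0, n_genes=400,
                              chromosome_length=8_000_000)
        ds = SyntheticDataset.generate(params)
        counts = np.stack(
            [ds.counts("control", replicate=r).to_numpy() for r in range(8)]
        )
        # variance/mean across seeds ~ 1 for Poisson draws
        ratio = counts.var(axis=0, ddof=1) / np.maximum(counts.mean(axis=0), 1)
        assert 0.5 < np.median(ratio) < 2.0

    def test_counts_reproducible_and_integer(self):
        ds = SyntheticDataset.generate(small_params(seed=9))
        c1 = ds.counts("knockdown")
        c2 = SyntheticDataset.generate(small_params(seed=9)).counts("knockdown")
        assert c1.equals(c2)
        assert (c1 >= 0).all()


class TestParameterRecovery:
    def test_si_fold_regression_on_true_spread_change(self, shift_si_tables,
                                                      shift_dataset):
        """Measured per-gene SI log-fold regressed on true delta-spread has a
        strongly positive slope at n=2000."""
        from h3k4spread.spreading import si_fold_change

        fold = si_fold_change(
            shift_si_tables["control"], shift_si_tables["knockdown"]
        )
        truth = shift_dataset.gene_truth.loc[fold.index, "delta_spread"]
        res = stats.linregress(truth, fold["log2_fold"])
        assert res.slope > 0
        assert res.pvalue < 1e-6
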