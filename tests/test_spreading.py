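"""Spreading index, SI fold change, ECDF, KS test, sliding windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h3k4spread.genome_io import MarkKind, ShortGeneError
from h3k4spread.spreading import (
    classify_delta_h3k4me3,
    ecdf,
    ks_two_sample,
    si_fold_change,
    sliding_window_fraction,
    spreading_index,
    spreading_table,
)

from conftest import make_gene, make_tags

MARK = MarkKind.from_name("H3K4me3")


def brute_force_si(positions, strands, ext, library_size, gene, mark,
                   floor=0.05):
    """Per-bp counting oracle for the spreading index."""
    span = max(int(p) for p in positions) + ext + 10
    cov = np.zeros(span + gene.interval.end + 10_000, dtype=np.int64)
    for p, s in zip(positions, strands):
        fs = p if s in (1, "+") else p - ext + 1
        fs = max(fs, 0)
        cov[fs:fs + ext] += 1
    hw = mark.promoter_halfwidth
    if gene.strand == "+":
        prom = (max(gene.tss - hw, 0), gene.tss + hw)
        body = (gene.tss + hw, gene.interval.end)
    else:
        prom = (max(gene.tss - hw, 0), gene.tss + hw)
        body = (gene.interval.start, gene.tss - hw)
    scale = library_size / 1e6
    prom_d = (cov[prom[0]:prom[1]].sum() / (prom[1] - prom[0])) / scale
    body_d = (cov[body[0]:body[1]].sum() / (body[1] - body[0])) / scale
    return prom_d, body_d, body_d / max(prom_d, floor)


class TestSpreadingIndex:
    def test_all_signal_in_promoter_gives_zero(self):
        gene = make_gene()
        tc = make_tags([10_000, 10_050, 9_900], fragment_extension=100)
        rec = spreading_index(tc, gene, MARK)
        assert rec.si == 0.0
        assert rec.promoter_density > 0

    def test_uniform_coverage_gives_si_one(self):
        # saturate promoter+body uniformly: one + tag every bp -> depth == ext
        gene = make_gene(start=10_000, end=14_000)
        pos = np.arange(9_000, 15_000)
        tc = make_tags(pos, fragment_extension=100)
        rec = spreading_index(tc, gene, MARK)
        assert rec.si == pytest.approx(1.0)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(10)
        gene = make_gene(start=10_000, end=20_000, strand="+")
        pos = rng.integers(8_000, 21_000, 400)
        strands = np.where(rng.random(400) < 0.5, 1, -1)
        tc = make_tags(pos, strands=strands, fragment_extension=150)
        rec = spreading_index(tc, gene, MARK)
        prom_d, body_d, si = brute_force_si(pos, strands, 150, 400, gene, MARK)
        assert rec.promoter_density == prom_d
        assert rec.body_density == body_d
        assert rec.si == si

    def test_short_gene_excluded(self):
        tc = make_tags([100])
        with pytest.raises(ShortGeneError):
            spreading_index(tc, make_gene(start=10_000, end=10_400), MARK)

    def test_library_duplication_invariance(self):
        rng = np.random.default_rng(11)
        gene = make_gene()
        tc = make_tags(rng.integers(9_000, 21_000, 300))
        rec = spreading_index(tc, gene, MARK)
        rec2 = spreading_index(tc.concatenate(tc), gene, MARK)
        assert rec2.si == rec.si  # RPBM scale cancels exactly in the ratio

    def test_table_agrees_with_single_gene_op(self, toy_annotation):
        rng = np.random.default_rng(12)
        pos = rng.integers(0, 60_000, 500)
        tc = make_tags(pos)
        table, excluded = spreading_table(tc, toy_annotation, MARK)
        assert excluded == []
        for gid in table.index:
            if toy_annotation[gid].chrom != "chr1":
                continue
            rec = spreading_index(tc, toy_annotation[gid], MARK)
            assert table.loc[gid, "si"] == rec.si


class TestSiFoldChange:
    def _table(self, si, prom=1.0):
        n = len(si)
        return pd.DataFrame(
            {
                "promoter_density": np.full(n, prom),
                "body_density": np.asarray(si) * prom,
                "si": np.asarray(si, dtype=float),
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_identical_conditions_give_fold_one(self):
        t = self._table([0.5, 1.0, 2.0])
        fold = si_fold_change(t, t)
        assert np.allclose(fold["fold"], 1.0)
        assert np.allclose(fold["log2_fold"], 0.0)

    def test_doubled_body_density_gives_fold_about_two(self):
        ctrl = self._table([1.0] * 5)
        kd = self._table([2.0] * 5)
        fold = si_fold_change(ctrl, kd)
        assert np.allclose(fold["fold"], 2.05 / 1.05)

    def test_unmatched_genes_excluded_and_counted(self):
        ctrl = self._table([1.0, 1.0, 1.0])
        kd = self._table([1.0, 1.0, 1.0, 1.0])
        fold = si_fold_change(ctrl, kd)
        assert len(fold) == 3
        assert fold.attrs["n_common"] == 3

    def test_unmarked_promoters_excluded(self):
        ctrl = self._table([1.0, 1.0], prom=0.01)  # below the 0.05 floor
        kd = self._table([1.0, 1.0], prom=0.01)
        with pytest.raises(ValueError):
            si_fold_change(ctrl.iloc[:0], kd)  # empty intersection
        fold = si_fold_change(ctrl, kd)
        assert len(fold) == 0
        assert fold.attrs["n_excluded_unmarked"] == 2


class TestEcdf:
    def test_basic_counting(self):
        f = ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)
        assert f(1.999) == pytest.approx(1 / 3)

    def test_bounds(self):
        f = ecdf([5.0, 1.0, 3.0])
        assert f(0.9999) == 0.0
        assert f(5.0) == 1.0

    def test_duplicates_create_double_step(self):
        f = ecdf([1.0, 2.0, 2.0, 3.0])
        assert f(2.0) - f(1.999999) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])


def brute_force_ks_d(a, b):
    """sup |F_a - F_b| by direct evaluation at every pooled point."""
    pooled = np.concatenate([a, b])
    best = 0.0
    for x in pooled:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_small_example_matches_enumeration(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        d, _ = ks_two_sample(a, b)
        assert d == brute_force_ks_d(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=37)
        b = rng.normal(0.5, size=23)
        d1, p1 = ks_two_sample(a, b)
        d2, p2 = ks_two_sample(b, a)
        assert d1 == d2 and p1 == p2
        assert 0 <= d1 <= 1 and 0 <= p1 <= 1

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])

    @given(
        a=st.lists(st.integers(0, 20), min_size=2, max_size=40),
        b=st.lists(st.integers(0, 20), min_size=2, max_size=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_d_matches_enumeration_property(self, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(brute_force_ks_d(a, b), abs=1e-12)


class TestSlidingWindow:
    def test_all_flagged(self):
        ordering = {f"g{i}": float(i) for i in range(10)}
        flags = {g: True for g in ordering}
        series = sliding_window_fraction(ordering, flags, window=4, step=2)
        assert np.allclose(series.fractions, 1.0)
        assert len(series) == (10 - 4) // 2 + 1

    def test_counting_example(self):
        ordering = {f"g{i}": float(i) for i in range(5)}
        flags = dict(zip(sorted(ordering), [True, False, True, False, False]))
        series = sliding_window_fraction(ordering, flags, window=3, step=1)
        assert np.allclose(series.fractions, [2 / 3, 1 / 3, 1 / 3])

    def test_window_equals_n_gives_overall_rate(self):
        ordering = {f"g{i}": float(i) for i in range(8)}
        flags = {g: (i % 4 == 0) for i, g in enumerate(sorted(ordering))}
        series = sliding_window_fraction(ordering, flags, window=8)
        assert len(series) == 1
        assert series.fractions[0] == pytest.approx(2 / 8)

    def test_window_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_fraction({"a": 1.0}, {"a": True}, window=2)

    def test_reversed_ordering_reverses_series(self):
        rng = np.random.default_rng(14)
        ordering = {f"g{i:03d}": float(v) for i, v in enumerate(rng.random(50))}
        flags = {g: bool(rng.integers(0, 2)) for g in ordering}
        fwd = sliding_window_fraction(ordering, flags, window=10, step=1)
        rev = sliding_window_fraction(
            {g: -v for g, v in ordering.items()}, flags, window=10, step=1
        )
        assert np.allclose(fwd.fractions, rev.fractions[::-1])


class TestClassifyDelta:
    def test_thresholds(self):
        ctrl = {"a": 1.0, "b": 1.0, "c": 1.0}
        ratio2 = {"a": 2.1, "b": 1.0, "c": 0.4}  # with p=0.05: >=1.5, 1, <=1/1.5
        labels = classify_delta_h3k4me3(ctrl, ratio2)
        assert labels["a"] == "increased"
        assert labels["b"] == "no_change"
        assert labels["c"] == "decreased"

    def test_boundary_counts_as_increased(self):
        # choose densities so the pseudocounted ratio is exactly 1.5
        ctrl = {"g": 0.95}
        treat = {"g": 1.45}  # (1.45+0.05)/(0.95+0.05) = 1.5
        labels = classify_delta_h3k4me3(ctrl, treat)
        assert labels["g"] == "increased"

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_delta_h3k4me3({"a": 1}, {"a": 1}, up_fold=0.9)
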