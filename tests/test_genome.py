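"""Interval algebra, signal quantification, and random-region sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from replilicense.genome import (
    BinnedTrack,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    coverage_fraction,
    intersect,
    sample_random_regions,
)

from conftest import (
    make_peaks,
    oracle_component_count,
    oracle_merge,
    peaks_as_tuples,
    random_peaks,
)


class TestLayoutAndIntervals:
    def test_layout_rejects_duplicates_and_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            GenomeLayout([("chr1", 10), ("chr1", 20)])
        with pytest.raises(ValueError):
            GenomeLayout([("chr1", 0)])

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_normalize_rejects_unknown_chromosome(self, toy_layout):
        with pytest.raises(KeyError, match="chrX"):
            make_peaks([("chrX", 0, 10)]).normalized(toy_layout)

    def test_chrom_sizes_roundtrip(self, toy_layout, tmp_path):
        path = tmp_path / "g.chrom.sizes"
        toy_layout.write_chrom_sizes(path)
        assert GenomeLayout.read_chrom_sizes(path) == toy_layout

    def test_bed_roundtrip(self, tmp_path):
        peaks = make_peaks([("chr1", 0, 10), ("chr2", 5, 15)])
        path = tmp_path / "p.bed"
        peaks.write_bed(path)
        back = PeakSet.read_bed(path)
        assert peaks_as_tuples(back) == peaks_as_tuples(peaks)


class TestIntersect:
    def test_two_components_one_unmatched(self, toy_layout):
        # a={[0,10),[20,30)}, b={[5,15),[25,28),[40,50)}: 2 components,
        # b-interval [40,50) unmatched (verified against the per-base oracle)
        a = make_peaks([("chr1", 0, 10), ("chr1", 20, 30)])
        b = make_peaks([("chr1", 5, 15), ("chr1", 25, 28), ("chr1", 40, 50)])
        comps, a_n, b_n = intersect(a, b, toy_layout)
        assert len(comps) == 2
        matched_b = {j for c in comps for j in c.b_indices}
        assert len(matched_b) == 2
        n_or, am, bm = oracle_component_count(a, b, toy_layout)
        assert len(comps) == n_or

    def test_empty_set_yields_no_components(self, toy_layout):
        comps, _, _ = intersect(PeakSet(), make_peaks([("chr1", 0, 10)]), toy_layout)
        assert comps == []

    def test_identical_sets_match_fully(self, toy_layout):
        p = make_peaks([("chr1", 0, 10), ("chr1", 100, 110), ("chr2", 50, 60)])
        comps, _, _ = intersect(p, p, toy_layout)
        assert len(comps) == 3
        assert all(c.a_indices == c.b_indices for c in comps)

    def test_unknown_chromosome_errors(self, toy_layout):
        with pytest.raises(KeyError, match="chrZ"):
            intersect(make_peaks([("chrZ", 0, 5)]), PeakSet(), toy_layout)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_per_base_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        layout = GenomeLayout([("c1", 2_000), ("c2", 1_000)])
        a = random_peaks(rng, layout, int(rng.integers(0, 15)), max_len=300)
        b = random_peaks(rng, layout, int(rng.integers(0, 15)), max_len=300)
        comps, a_n, b_n = intersect(a, b, layout)
        n_or, am_or, bm_or = oracle_component_count(a_n, b_n, layout)
        assert len(comps) == n_or
        assert {i for c in comps for i in c.a_indices} == am_or
        assert {j for c in comps for j in c.b_indices} == bm_or


class TestMerge:
    def test_overlapping_pair(self):
        merged = make_peaks([("chr1", 0, 10), ("chr1", 5, 20)]).merge()
        assert peaks_as_tuples(merged) == [("chr1", 0, 20)]

    def test_disjoint_unchanged(self):
        p = make_peaks([("chr1", 0, 10), ("chr1", 50, 60)])
        assert peaks_as_tuples(p.merge()) == peaks_as_tuples(p)

    def test_gap_bridges_small_separation(self):
        merged = make_peaks([("chr1", 0, 10), ("chr1", 12, 20)]).merge(gap=2)
        assert peaks_as_tuples(merged) == [("chr1", 0, 20)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            make_peaks([("chr1", 0, 10)]).merge(gap=-1)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10))
    def test_matches_per_base_oracle(self, seed, gap):
        rng = np.random.default_rng(seed)
        layout = GenomeLayout([("c1", 1_500)])
        p = random_peaks(rng, layout, int(rng.integers(0, 12)), max_len=200)
        assert peaks_as_tuples(p.merge(gap)) == oracle_merge(p, layout, gap)

    def test_merge_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(7)
        layout = GenomeLayout([("c1", 5_000)])
        p = random_peaks(rng, layout, 30, max_len=400)
        m1 = p.merge()
        assert peaks_as_tuples(m1.merge()) == peaks_as_tuples(m1)
        shuffled = PeakSet(p.df.sample(frac=1, random_state=1))
        duplicated = PeakSet(pd.concat([p.df, p.df], ignore_index=True))
        for variant in (shuffled, duplicated):
            assert coverage_fraction(variant, layout) == coverage_fraction(p, layout)


class TestMeanSignal:
    def test_constant_track(self, toy_layout):
        t = BinnedTrack.constant(toy_layout, 100, 3.5)
        assert t.mean_signal(GenomicInterval("chr1", 37, 4_012)) == pytest.approx(3.5)

    def test_weighted_mean_across_bins(self):
        layout = GenomeLayout([("c", 20)])
        t = BinnedTrack(10, {"c": np.array([1.0, 3.0])}, layout)
        assert t.mean_signal(GenomicInterval("c", 5, 15)) == pytest.approx(2.0)

    def test_single_bin_returns_bin_value(self):
        layout = GenomeLayout([("c", 20)])
        t = BinnedTrack(10, {"c": np.array([1.0, 3.0])}, layout)
        assert t.mean_signal(GenomicInterval("c", 10, 20)) == pytest.approx(3.0)

    def test_whole_genome_equals_global_weighted_mean(self):
        rng = np.random.default_rng(3)
        layout = GenomeLayout([("c1", 1_050), ("c2", 800)])  # partial last bin
        t = BinnedTrack(
            100,
            {"c1": rng.random(11), "c2": rng.random(8)},
            layout,
        )
        per_chrom = [
            t.mean_signal(GenomicInterval(c, 0, layout.length(c))) * layout.length(c)
            for c in layout.names
        ]
        assert sum(per_chrom) / layout.total_bp == pytest.approx(t.global_mean())

    def test_bedgraph_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        layout = GenomeLayout([("c1", 1_050)])
        t = BinnedTrack(100, {"c1": np.round(rng.random(11), 6)}, layout)
        path = tmp_path / "t.bedgraph"
        t.write_bedgraph(path)
        back = BinnedTrack.read_bedgraph(path, layout)
        assert back.bin_width == 100
        np.testing.assert_allclose(back.values["c1"], t.values["c1"])


class TestRandomRegions:
    def test_deterministic_given_seed(self, toy_layout):
        a = sample_random_regions(toy_layout, 50, [10, 20, 30], rng_seed=42)
        b = sample_random_regions(toy_layout, 50, [10, 20, 30], rng_seed=42)
        assert peaks_as_tuples(a) == peaks_as_tuples(b)

    def test_forced_placement_on_exact_fit(self, tiny_layout):
        p = sample_random_regions(tiny_layout, 3, [1_000], rng_seed=0)
        assert peaks_as_tuples(p) == [("chrT", 0, 1_000)] * 3

    def test_zero_draws_empty(self, toy_layout):
        assert len(sample_random_regions(toy_layout, 0, [10], rng_seed=0)) == 0

    def test_length_exceeding_genome_rejected(self, tiny_layout):
        with pytest.raises(ValueError):
            sample_random_regions(tiny_layout, 1, [2_000], rng_seed=0)

    def test_start_positions_uniform(self):
        layout = GenomeLayout([("c", 10_000)])
        p = sample_random_regions(layout, 10_000, [1], rng_seed=123)
        starts = p.df["start"].to_numpy()
        observed, _ = np.histogram(starts, bins=20, range=(0, 10_000))
        chi2 = ((observed - 500.0) ** 2 / 500.0).sum()
        assert stats.chi2.sf(chi2, df=19) > 0.001


class TestCoverageFraction:
    def test_empty_and_full(self, tiny_layout):
        assert coverage_fraction(PeakSet(), tiny_layout) == 0.0
        assert coverage_fraction(make_peaks([("chrT", 0, 1_000)]), tiny_layout) == 1.0

    def test_partial(self, tiny_layout):
        assert coverage_fraction(make_peaks([("chrT", 0, 100)]), tiny_layout) == pytest.approx(0.1)


class TestSubtract:
    def test_clips_overlap(self):
        a = make_peaks([("chr1", 0, 100)])
        b = make_peaks([("chr1", 50, 150)])
        assert peaks_as_tuples(a.subtract(b)) == [("chr1", 0, 50)]

    def test_empty_subtrahend_identity(self):
        a = make_peaks([("chr1", 0, 100), ("chr2", 5, 9)])
        assert peaks_as_tuples(a.subtract(PeakSet())) == peaks_as_tuples(a)
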