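"""Read QC, trimming, duplicate marking, downsampling and coverage."""

import numpy as np
import pytest

import depthdesign as dd
from depthdesign.readops import round_depth_label

from conftest import build_readset, genome_from

PAPER_DEPTH_LABELS = [1.09, 2.18, 3.26, 4.35, 6.53, 8.70, 10.88,
                      13.05, 15.22, 17.40, 19.57, 21.75]


def _pair(start1, start2, q1, q2, **kw):
    return [
        dict(start=start1, quals=q1, mate_offset=+1, **kw),
        dict(start=start2, quals=q2, mate_offset=-1, is_reverse=True, **kw),
    ]


class TestQCFilter:
    def test_read_exceeding_lowq_fraction_removed_with_mate(self):
        q_bad = [20] * 31 + [30] * 69  # 31% at Q20
        rs = build_readset(_pair(0, 200, q_bad, (30, 100)))
        out = dd.qc_filter_reads(rs, 0.30, 20)
        assert out.n_reads == 0

    def test_boundary_fraction_kept(self):
        q_edge = [20] * 30 + [30] * 70  # exactly 30%, 'more than' is strict
        rs = build_readset(_pair(0, 200, q_edge, (30, 100)))
        out = dd.qc_filter_reads(rs, 0.30, 20)
        assert out.n_reads == 2

    def test_clean_reads_identity(self):
        rs = build_readset(_pair(0, 200, (30, 100), (30, 100)))
        out = dd.qc_filter_reads(rs)
        assert out.n_reads == 2
        out.check_pairing()

    def test_empty_input(self):
        rs = build_readset([])
        assert dd.qc_filter_reads(rs).n_reads == 0


class TestTrim3Prime:
    def test_trailing_lowq_removed_forward(self):
        rs = build_readset(_pair(0, 200, [30] * 8 + [10, 10], (30, 10)))
        out = dd.trim_3prime(rs, 20)
        assert out.length[0] == 8
        assert out.start[0] == 0

    def test_reverse_read_trims_reference_left(self):
        # reverse read: 3' end is the low-coordinate side of the window
        rs = build_readset(_pair(0, 200, (30, 10), [10, 10] + [30] * 8))
        out = dd.trim_3prime(rs, 20)
        assert out.length[1] == 8
        assert out.start[1] == 202  # shifted past the trimmed bases

    def test_all_above_threshold_unchanged(self):
        rs = build_readset(_pair(0, 200, (30, 10), (30, 10)))
        out = dd.trim_3prime(rs, 20)
        np.testing.assert_array_equal(out.length, [10, 10])

    def test_fully_lowq_read_dropped_with_mate(self):
        rs = build_readset(_pair(0, 200, (5, 10), (30, 10)))
        out = dd.trim_3prime(rs, 20)
        assert out.n_reads == 0


class TestMarkDuplicates:
    def test_identical_pairs_one_flagged(self):
        rs = build_readset(_pair(0, 200, (30, 100), (30, 100))
                           + _pair(0, 200, (30, 100), (30, 100)))
        out = dd.mark_duplicates(rs)
        dup_pairs = {int(p) for p, d in zip(out.pair_id, out.is_dup) if d}
        assert len(dup_pairs) == 1

    def test_distinct_coordinates_unflagged(self):
        rs = build_readset(_pair(0, 200, (30, 100), (30, 100))
                           + _pair(50, 250, (30, 100), (30, 100)))
        out = dd.mark_duplicates(rs)
        assert not out.is_dup.any()

    def test_quality_then_name_tie_break(self):
        # summed pair qualities 300/280/300: the tie between pairs p0 and
        # p2 resolves to the lexicographically smaller name p0
        rs = build_readset(
            _pair(0, 200, (15, 10), (15, 10))   # p0: 300
            + _pair(0, 200, (14, 10), (14, 10))  # p1: 280
            + _pair(0, 200, (15, 10), (15, 10))  # p2: 300
        )
        out = dd.mark_duplicates(rs)
        kept = {int(p) for p, d in zip(out.pair_id, out.is_dup) if not d}
        assert kept == {0}


class TestDownsample:
    def test_proportion_one_identity(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        tier = dd.downsample(rs, 1.0, 1)
        assert tier.read_subset is rs

    def test_proportion_zero_empty(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        assert dd.downsample(rs, 0.0, 1).read_subset.n_reads == 0

    def test_out_of_range_rejected(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        with pytest.raises(ValueError):
            dd.downsample(rs, 1.5, 1)

    def test_kept_count_binomial_and_pairs_intact(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        n_pairs = rs.n_reads // 2
        tier = dd.downsample(rs, 0.5, 123)
        kept_pairs = tier.read_subset.n_reads // 2
        sd = np.sqrt(n_pairs * 0.25)
        assert abs(kept_pairs - 0.5 * n_pairs) < 3 * sd
        tier.read_subset.check_pairing()
        assert (tier.read_subset.mate >= 0).all()


class TestDepthLadder:
    def test_nominal_depths_match_printed_ladder(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        tiers = dd.build_depth_ladder(rs, dd.PAPER_PROPORTIONS, 21.75, 5)
        labels = [round_depth_label(t.proportion * 21.75) for t in tiers]
        assert len(labels) == 12
        np.testing.assert_allclose(labels, PAPER_DEPTH_LABELS, atol=0.011)

    def test_single_proportion_gives_tier_plus_full(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        tiers = dd.build_depth_ladder(rs, [0.5], 21.75, 5)
        assert [t.proportion for t in tiers] == [0.5, 1.0]

    def test_ladder_is_nested(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        tiers = dd.build_depth_ladder(rs, dd.PAPER_PROPORTIONS, 21.75, 5)
        for lo, hi in zip(tiers, tiers[1:]):
            lo_pairs = set(lo.read_subset.pair_id.tolist())
            hi_pairs = set(hi.read_subset.pair_id.tolist())
            assert lo_pairs <= hi_pairs

    def test_non_monotone_rejected(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        with pytest.raises(ValueError):
            dd.build_depth_ladder(rs, [0.5, 0.3], 21.75, 5)

    def test_breadth_monotone_along_ladder(self, small_cohort):
        rs = dd.simulate_reads(small_cohort, 0)
        tiers = dd.build_depth_ladder(rs, [0.1, 0.3, 0.6], 21.75, 5)
        vals = [dd.compute_depth_and_coverage(t, small_cohort.genome)
                for t in tiers]
        depths = [v[0] for v in vals]
        breadths = [v[1] for v in vals]
        assert depths == sorted(depths)
        assert breadths == sorted(breadths)


class TestDepthAndCoverage:
    def test_empty_tier(self):
        g = genome_from("ACGT" * 50)
        assert dd.compute_depth_and_coverage(build_readset([]), g) == (0.0, 0.0)

    def test_single_read_full_genome(self):
        g = genome_from("A" * 150)
        rs = build_readset([dict(start=0, quals=(30, 150))])
        assert dd.compute_depth_and_coverage(rs, g) == (1.0, 1.0)

    def test_duplicates_excluded_by_default(self):
        g = genome_from("A" * 200)
        rs = build_readset([
            dict(start=0, quals=(30, 100)),
            dict(start=100, quals=(30, 100), is_dup=True),
        ])
        depth, breadth = dd.compute_depth_and_coverage(rs, g)
        assert (depth, breadth) == (0.5, 0.5)
        depth, breadth = dd.compute_depth_and_coverage(rs, g, exclude_duplicates=False)
        assert (depth, breadth) == (1.0, 1.0)

    def test_breadth_near_lander_waterman(self, small_cohort):
        cfg = dd.SimConfig(genome_length=200_000, mean_depth=10.0,
                           duplicate_rate=0.0, seed=42)
        rs = dd.simulate_reads(small_cohort, 0, cfg)
        depth, breadth = dd.compute_depth_and_coverage(rs, small_cohort.genome)
        expected = dd.lander_waterman_breadth(depth)
        assert abs(breadth - expected) < 0.005


def test_qc_commutes_with_downsampling_in_expectation(small_cohort):
    """Filtering then sampling should keep the same fraction as sampling
    then filtering (the operations act on independent read attributes)."""
    rs = dd.simulate_reads(small_cohort, 1)
    a = dd.downsample(dd.qc_filter_reads(rs), 0.5, 7).read_subset.n_reads
    b = dd.qc_filter_reads(dd.downsample(rs, 0.5, 7).read_subset).n_reads
    n = rs.n_reads
    assert abs(a - b) < 3 * np.sqrt(n * 0.25) * 2
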