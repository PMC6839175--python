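"""Genotype likelihoods, the exact allele-count posterior, annotations,
and agreement between the batch caller and the per-column machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import depthdesign as dd
from depthdesign.caller import PileupColumn, SampleEvidence, ac_prior_log10

from conftest import build_readset, genome_from


def make_column(bases, quals=None, mapq=60, pos=100, ref="A", sample="S1",
                strands=None, offsets=None):
    n = len(bases)
    ev = SampleEvidence(
        bases=np.array(list(bases)),
        base_qual=np.array(quals if quals is not None else [30] * n),
        map_qual=np.array([mapq] * n if np.isscalar(mapq) else mapq),
        is_reverse=np.array(strands if strands is not None else [False] * n),
        offset_from_read_end=np.array(offsets if offsets is not None else [10] * n),
    )
    return PileupColumn("chr1", pos, ref, {sample: ev})


def ac_data_bruteforce(gl_log10):
    """Exhaustive enumeration oracle for P(D|AC=i) (normalized GLs)."""
    gl = np.asarray(gl_log10, float).reshape(-1, 3)
    lin = 10.0 ** (gl - gl.max(axis=1, keepdims=True))
    n = gl.shape[0]
    out = np.zeros(2 * n + 1)
    for cfg in itertools.product(range(3), repeat=n):
        w = 1.0
        for s, g in enumerate(cfg):
            w *= lin[s, g] * math.comb(2, g)
        out[sum(cfg)] += w
    for i in range(2 * n + 1):
        out[i] /= math.comb(2 * n, i)
    return out


class TestGenotypeLikelihood:
    def test_two_alt_reads_q20_hand_values(self):
        col = make_column("GG", quals=[20, 20], ref="A")
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        lin = 10.0 ** gl.gl
        eps = 0.01
        np.testing.assert_allclose(lin[0], (eps / 3) ** 2, rtol=1e-12)
        np.testing.assert_allclose(
            lin[1], (0.5 * eps / 3 + 0.5 * (1 - eps)) ** 2, rtol=1e-12
        )
        np.testing.assert_allclose(lin[2], (1 - eps) ** 2, rtol=1e-12)

    def test_zero_reads_flat(self):
        col = PileupColumn("chr1", 1, "A", {})
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        np.testing.assert_array_equal(gl.gl, [0.0, 0.0, 0.0])

    def test_balanced_reads_favor_het(self):
        col = make_column("AAAAAGGGGG", ref="A")
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        assert gl.gl.argmax() == 1

    def test_base_quality_capped_by_mapping_quality(self):
        hi = dd.genotype_likelihood(make_column("G", quals=[40], mapq=60), "S1", "A", "G")
        lo = dd.genotype_likelihood(make_column("G", quals=[40], mapq=10), "S1", "A", "G")
        assert lo.gl[0] > hi.gl[0]  # low MQ weakens evidence against hom-ref

    def test_third_allele_reads_ignored(self):
        with_noise = dd.genotype_likelihood(make_column("GGT", ref="A"), "S1", "A", "G")
        clean = dd.genotype_likelihood(make_column("GG", ref="A"), "S1", "A", "G")
        np.testing.assert_allclose(with_noise.gl, clean.gl)


class TestAlleleCountPosterior:
    @pytest.mark.parametrize("n_samples", [1, 2, 3, 4])
    def test_dp_matches_enumeration(self, n_samples):
        rng = np.random.default_rng(n_samples)
        for _ in range(20):
            gl = rng.uniform(-30, 0, size=(n_samples, 3))
            got = dd.ac_likelihoods(gl)
            want = ac_data_bruteforce(gl)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_prior_mass_sums_to_one(self):
        for n in (1, 3, 5):
            p = 10.0 ** ac_prior_log10(n, 1e-3)
            np.testing.assert_allclose(p.sum(), 1.0, rtol=1e-12)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            ac_prior_log10(3, 0.0)
        with pytest.raises(ValueError):
            ac_prior_log10(3, 0.9)

    def test_no_reads_site_not_emitted(self):
        gl = np.zeros((3, 3))
        call = dd.call_site_multi(gl, theta=1e-3, emit_conf=30.0)
        assert call is None
        # posterior equals prior: qual is -10 log10 P(AC=0)
        call = dd.call_site_multi(gl, theta=1e-3, emit_conf=0.0)
        p0 = 10.0 ** ac_prior_log10(3, 1e-3)[0]
        np.testing.assert_allclose(call.qual, -10 * np.log10(p0), rtol=1e-9)

    def test_single_sample_is_multi_with_n1(self):
        gl = np.array([[-8.0, -0.2, -3.0]])
        a = dd.call_site_single(dd.GenotypeLikelihoods("chr1", 5, "S1", gl[0]))
        b = dd.call_site_multi(gl, samples=["S1"], pos=5)
        assert a.qual == pytest.approx(b.qual)
        assert a.genotypes == b.genotypes

    def test_qual_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(0)
        gl = rng.uniform(-20, 0, size=(3, 3))
        a = dd.call_site_multi(gl, emit_conf=0.0)
        b = dd.call_site_multi(gl[::-1].copy(), emit_conf=0.0)
        assert a.qual == pytest.approx(b.qual, rel=1e-12)


class TestSingleSampleCalls:
    def test_clean_hom_alt(self):
        col = make_column("G" * 20, ref="A")
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        call = dd.call_site_single(gl, ref="A", alt="G")
        assert call is not None and call.qual >= 30
        assert call.genotypes["S1"] == 2

    def test_clean_hom_ref_not_emitted(self):
        col = make_column("A" * 20, ref="A")
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        assert dd.call_site_single(gl) is None

    def test_balanced_het(self):
        col = make_column("A" * 10 + "G" * 10, ref="A")
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        call = dd.call_site_single(gl)
        assert call is not None and call.genotypes["S1"] == 1


class TestPileup:
    def test_no_reads_empty(self):
        g = genome_from("ACGT" * 10)
        assert list(dd.pileup(build_readset([]), g)) == []

    def test_single_read_columns(self):
        g = genome_from("ACGTACGTACGT")
        rs = build_readset([dict(start=4, quals=(30, 3))])
        cols = list(dd.pileup(rs, g))
        assert [c.pos for c in cols] == [5, 6, 7]
        assert all(c.samples["S1"].depth == 1 for c in cols)
        assert [c.ref for c in cols] == ["A", "C", "G"]

    def test_depths_match_interval_stabbing_oracle(self):
        g = genome_from("A" * 300)
        rng = np.random.default_rng(4)
        reads = [dict(start=int(s), quals=(30, int(l)))
                 for s, l in zip(rng.integers(0, 250, 30), rng.integers(5, 50, 30))]
        rs = build_readset(reads)
        depth_by_pos = {c.pos: c.samples["S1"].depth for c in dd.pileup(rs, g)}
        for pos in range(1, 301):
            naive = sum(
                1 for r in reads if r["start"] + 1 <= pos <= r["start"] + r["quals"][1]
            )
            assert depth_by_pos.get(pos, 0) == naive

    def test_read_overrunning_chromosome_rejected(self):
        g = genome_from("ACGT")
        rs = build_readset([dict(start=2, quals=(30, 10))])
        with pytest.raises(ValueError):
            list(dd.pileup(rs, g))


class TestAnnotations:
    def test_fisher_strand_symmetric_table_zero(self):
        assert dd.fisher_strand(10, 10, 10, 10) == 0.0

    def test_fisher_strand_perfect_imbalance(self):
        # table (5,0 / 0,5): two-sided p = 2/252
        fs = dd.fisher_strand(5, 0, 0, 5)
        np.testing.assert_allclose(fs, -10 * np.log10(2 / 252), rtol=1e-6)

    def test_rms_mapping_quality(self):
        assert dd.rms_mapping_quality([60] * 8) == 60.0
        np.testing.assert_allclose(dd.rms_mapping_quality([40, 60]),
                                   np.sqrt((1600 + 3600) / 2))

    def test_rank_sum_identical_groups_near_zero(self):
        z = dd.rank_sum_z([60] * 5, [60] * 5)
        assert z == 0.0

    def test_rank_sum_absent_when_group_empty(self):
        assert dd.rank_sum_z([], [1, 2, 3]) is None

    def test_rank_sum_sign_convention(self):
        # alt reads with lower mapping quality -> negative z
        assert dd.rank_sum_z([10, 12, 11], [60, 58, 59]) < 0
        assert dd.rank_sum_z([60, 58, 59], [10, 12, 11]) > 0

    def test_rank_sum_magnitude_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a = rng.integers(0, 60, size=rng.integers(2, 12))
            b = rng.integers(0, 60, size=rng.integers(2, 12))
            z = dd.rank_sum_z(a, b)
            p = mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=True, method="asymptotic").pvalue
            from scipy.stats import norm
            np.testing.assert_allclose(abs(z), abs(norm.ppf(p / 2)), atol=1e-8)

    def test_annotate_attaches_expected_keys(self):
        col = make_column("A" * 6 + "G" * 6, ref="A",
                          strands=[False, True] * 6,
                          offsets=list(range(12)))
        gl = dd.genotype_likelihood(col, "S1", "A", "G")
        call = dd.call_site_single(gl, ref="A", alt="G")
        call = dd.annotate(call, {"S1": col})
        for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
            assert key in call.annotations
        assert call.annotations["MQ"] == 60.0
        assert call.annotations["QD"] == pytest.approx(call.qual / 12)


class TestBatchCaller:
    def test_batch_agrees_with_per_column_machinery(self):
        cfg = dd.SimConfig(genome_length=30_000, mean_depth=15.0,
                           duplicate_rate=0.0, seed=21)
        coh = dd.simulate_cohort(cfg)
        readsets = {s: dd.simulate_reads(coh, i, cfg)
                    for i, s in enumerate(coh.sample_names)}
        calls = dd.call_variants(readsets, coh.genome)
        snps = calls[calls["vclass"] == "SNP"]
        assert len(snps) > 10
        checked = 0
        columns = {
            s: {c.pos: c for c in dd.pileup(rs, coh.genome, s)}
            for s, rs in readsets.items()
        }
        for _, row in snps.head(25).iterrows():
            gls = []
            for s in coh.sample_names:
                col = columns[s].get(row["pos"])
                if col is None:
                    col = PileupColumn(row["chrom"], row["pos"], row["ref"], {})
                gls.append(dd.genotype_likelihood(col, s, row["ref"], row["alt"]))
            ref_call = dd.call_site_multi(gls, emit_conf=0.0,
                                          samples=coh.sample_names)
            assert ref_call.qual == pytest.approx(row["qual"], rel=1e-6)
            for s in coh.sample_names:
                assert ref_call.genotypes[s] == row[f"GT_{s}"]
            checked += 1
        assert checked > 0

    def test_emitted_sites_have_two_plus_alt_reads(self):
        """A site reaching confidence 30 always has >=2 alt reads under the
        Q40 error floor, so the candidate prefilter loses nothing."""
        gl_one_alt = np.zeros((1, 3))
        eps = 1e-4  # Q40 floor
        gl_one_alt[0] = [np.log10(eps / 3),
                         np.log10(0.5 * (1 - eps) + 0.5 * eps / 3),
                         np.log10(1 - eps)]
        call = dd.call_site_multi(gl_one_alt, emit_conf=30.0)
        assert call is None
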