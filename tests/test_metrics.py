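"""Depth-response and chip-validation metric definitions."""

import numpy as np
import pandas as pd
import pytest

from depthdesign import metrics as M
from depthdesign.synthio import ChipPanel


def key_set(*keys):
    return {("chr1", p, r, a) for p, r, a in keys}


def calls_from_keys(keys, gt=None, sample="S1"):
    rows = [
        dict(chrom=c, pos=p, ref=r, alt=a, vclass="SNP",
             **{f"GT_{sample}": (gt or {}).get((c, p), 1)})
        for c, p, r, a in sorted(keys)
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass",
                                     f"GT_{sample}"])
    df.attrs["samples"] = [sample]
    df.attrs["panel_samples"] = [sample]
    return df


class TestDiscoveryPower:
    def test_full_set_gives_one(self):
        full = key_set((1, "A", "G"), (2, "C", "T"))
        assert M.discovery_power(full, full) == 1.0

    def test_empty_tier_gives_zero(self):
        full = key_set((1, "A", "G"))
        assert M.discovery_power(set(), full) == 0.0

    def test_partial_overlap(self):
        full = {("chr1", i, "A", "G") for i in range(200)}
        tier = {("chr1", i, "A", "G") for i in range(90)} | {
            ("chr2", i, "A", "G") for i in range(500, 560)
        }
        assert M.discovery_power(tier, full) == pytest.approx(0.45)

    def test_empty_full_set_absent(self):
        assert M.discovery_power(key_set((1, "A", "G")), set()) is None


class TestNovelRate:
    def test_all_known_gives_zero(self):
        calls = key_set((1, "A", "G"), (5, "C", "T"))
        assert M.novel_rate(calls, calls) == 0.0

    def test_fifteen_percent_absent(self):
        calls = {("chr1", i, "A", "G") for i in range(100)}
        known = {("chr1", i, "A", "G") for i in range(15, 100)}
        assert M.novel_rate(calls, known) == pytest.approx(0.15)

    def test_disjoint_gives_one(self):
        calls = key_set((1, "A", "G"))
        known = key_set((2, "A", "G"))
        assert M.novel_rate(calls, known) == 1.0

    def test_empty_calls_absent(self):
        assert M.novel_rate(set(), key_set((1, "A", "G"))) is None


class TestTiTv:
    def test_mixed_set(self):
        calls = key_set((1, "A", "G"), (2, "G", "A"), (3, "C", "T"), (4, "A", "C"))
        assert M.titv_ratio(calls) == 3.0

    def test_all_transversions_zero(self):
        calls = key_set((1, "A", "C"), (2, "G", "T"))
        assert M.titv_ratio(calls) == 0.0

    def test_no_transversions_absent(self):
        assert M.titv_ratio(key_set((1, "A", "G"))) is None

    def test_recovers_simulated_bias(self, small_cohort):
        realized = M.titv_ratio(small_cohort.truth_snps())
        assert abs(realized - 2.2) < 0.35  # sampling error at ~550 SNPs


def make_panel(positions, call_rates=None, genotypes=None):
    n = len(positions)
    sites = pd.DataFrame(
        dict(
            chrom=["chr1"] * n,
            pos=positions,
            allele_a=["A"] * n,
            allele_b=["G"] * n,
            call_rate=call_rates or [1.0] * n,
        )
    )
    g = np.asarray(genotypes if genotypes is not None else np.ones((1, n)), np.int8)
    return ChipPanel(sites, g)


class TestChipQC:
    def test_low_call_rate_excluded_boundary_retained(self):
        panel = make_panel([10, 20, 30], call_rates=[0.94, 0.95, 1.0],
                           genotypes=np.ones((1, 3)))
        out = M.chip_qc(panel, 0.95)
        assert out.sites["pos"].tolist() == [20, 30]
        assert out.genotypes.shape == (1, 2)

    def test_off_chromosome_sites_dropped(self):
        panel = make_panel([10, 20], genotypes=np.ones((1, 2)))
        panel.sites.loc[1, "chrom"] = "chrX"
        out = M.chip_qc(panel, 0.95, chrom_names=["chr1"])
        assert out.sites["pos"].tolist() == [10]

    def test_identity_when_all_pass(self):
        panel = make_panel([10, 20])
        out = M.chip_qc(panel, 0.95)
        assert out.n_sites == 2


class TestCommonSites:
    def test_disjoint_positions_empty(self):
        calls = calls_from_keys(key_set((5, "A", "G")))
        panel = make_panel([100])
        assert M.common_sites(calls, panel) == set()

    def test_hom_ref_site_split_by_mode(self):
        calls = calls_from_keys(key_set((100, "A", "G")), gt={("chr1", 100): 0})
        panel = make_panel([100])
        assert M.common_sites(calls, panel, "all") == {("chr1", 100)}
        assert M.common_sites(calls, panel, "alt_only", "S1") == set()

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(5)
        call_pos = sorted(rng.choice(1000, 80, replace=False).tolist())
        panel_pos = sorted(rng.choice(1000, 60, replace=False).tolist())
        calls = calls_from_keys({("chr1", p, "A", "G") for p in call_pos})
        panel = make_panel(panel_pos, genotypes=np.ones((1, len(panel_pos))))
        naive = {("chr1", p) for p in call_pos if p in set(panel_pos)}
        assert M.common_sites(calls, panel) == naive


class TestDiscordance:
    def test_identical_genotypes_zero(self):
        calls = calls_from_keys(key_set((10, "A", "G"), (20, "A", "G")))
        panel = make_panel([10, 20], genotypes=[[1, 1]])
        assert M.discordance_rate(calls, panel, "S1") == 0.0

    def test_simple_fraction(self):
        pos = list(range(1, 1001))
        gt = {("chr1", p): 1 for p in pos}
        calls = calls_from_keys({("chr1", p, "A", "G") for p in pos}, gt=gt)
        chip = np.ones((1, 1000), np.int8)
        chip[0, :32] = 2  # 32 mismatching sites
        panel = make_panel(pos, genotypes=chip)
        assert M.discordance_rate(calls, panel, "S1") == pytest.approx(0.032)

    def test_het_vs_hom_alt_counts_as_mismatch(self):
        calls = calls_from_keys(key_set((10, "A", "G")), gt={("chr1", 10): 1})
        panel = make_panel([10], genotypes=[[2]])
        assert M.discordance_rate(calls, panel, "S1") == 1.0

    def test_chip_missing_excluded(self):
        calls = calls_from_keys(key_set((10, "A", "G"), (20, "A", "G")))
        panel = make_panel([10, 20], genotypes=[[-1, 1]])
        assert M.discordance_rate(calls, panel, "S1") == 0.0

    def test_empty_common_absent(self):
        calls = calls_from_keys(key_set((5, "A", "G")))
        panel = make_panel([100])
        assert M.discordance_rate(calls, panel, "S1") is None


class TestFoldChange:
    def test_equal_counts(self):
        assert M.fold_change_multi_vs_single(10, 10) == 1.0

    def test_headline_ratio(self):
        assert M.fold_change_multi_vs_single(2600, 200) == 13.0

    def test_zero_single_absent(self):
        assert M.fold_change_multi_vs_single(5, 0) is None


class TestIntersectPopulations:
    def test_identical_sets(self):
        s = key_set((1, "A", "G"), (2, "C", "T"))
        out = M.intersect_populations({"D": s, "L": s, "Y": s})
        assert out["D&L"] == out["D&L&Y"] == 2

    def test_disjoint_sets(self):
        out = M.intersect_populations(
            {"D": key_set((1, "A", "G")), "L": key_set((2, "A", "G"))}
        )
        assert out["D&L"] == 0

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(11)
        sets = {
            name: {("chr1", int(p), "A", "G") for p in rng.choice(200, 50, replace=False)}
            for name in ("D", "L", "Y")
        }
        out = M.intersect_populations(sets)
        assert out["D&L"] == len(sets["D"] & sets["L"])
        assert out["D&L&Y"] == len(sets["D"] & sets["L"] & sets["Y"])

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            M.intersect_populations({"D": set()})


def test_genotype_concordance_counts_matching_dosages():
    truth = pd.DataFrame(
        dict(chrom=["chr1"] * 3, pos=[10, 20, 30], ref=["A"] * 3, alt=["G"] * 3)
    )
    genotypes = np.array([[1], [2], [1]])
    calls = calls_from_keys(
        key_set((10, "A", "G"), (20, "A", "G"), (30, "A", "G")),
        gt={("chr1", 10): 1, ("chr1", 20): 2, ("chr1", 30): 2},
    )
    conc = M.genotype_concordance(calls, truth, genotypes, "S1", 0)
    assert conc == pytest.approx(2 / 3)
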