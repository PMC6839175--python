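"""Synthetic cohort generator: genome, truth variants, reads, known
sites and a genotyping-array panel, all pure functions of (config, seed).

The generator emulates a small diploid resequencing study: a uniform
random reference; biallelic SNPs and short indels placed at a configured
density with a transition:transversion bias; a population allele
frequency per variant (shared by every individual, so several groups of
individuals drawn from the same cohort behave like breeds sharing a
site-frequency spectrum); Hardy-Weinberg diploid genotypes; uniformly
placed 150-bp paired-end reads with per-base qualities, injected
sequencing errors, mapping qualities and PCR-duplicate pairs; a
dbSNP-like known-sites list covering a configurable fraction of truth;
and a chip panel holding truth genotypes at a subset of SNP sites with
per-site call rates.

Base qualities follow a constant Q30 baseline; injected errors are
assigned a low quality (Q <= 20) with probability 0.8, so the read-QC
rule has realistic bite. Fragment placement is uniform (no GC bias),
which puts the simulator in the Lander-Waterman regime the coverage
analysis is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, decode_seq, transition_partner
from .readops import ReadSet

PAPER_PROPORTIONS = (0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults are the desk-scale rendering of the study conditions:
    ~20X 150-bp paired-end sequencing of 3 individuals over a 1 Mb
    reference, one variant per ~300 bp split 9:1 SNP:indel, whole-genome
    Ti/Tv bias 2.2, a known-sites list holding 85% of truth, and a chip
    covering a fifth of truth SNP sites.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    n_individuals: int = 3
    variant_density: float = 1 / 300
    snp_fraction: float = 0.9
    titv_bias: float = 2.2
    max_indel_len: int = 10
    mean_depth: float = 21.75
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.001
    lowqual_error_fraction: float = 0.8
    baseline_qual: int = 30
    duplicate_rate: float = 0.01
    mapq_high: int = 60
    mapq_low_fraction: float = 0.03
    dbsnp_fraction: float = 0.85
    known_extra: int = 0  # known-sites entries absent from truth
    chip_fraction: float = 0.2
    chip_missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "variant_density": self.variant_density,
            "snp_fraction": self.snp_fraction,
            "base_error_rate": self.base_error_rate,
            "lowqual_error_fraction": self.lowqual_error_fraction,
            "duplicate_rate": self.duplicate_rate,
            "mapq_low_fraction": self.mapq_low_fraction,
            "dbsnp_fraction": self.dbsnp_fraction,
            "chip_fraction": self.chip_fraction,
            "chip_missing_rate": self.chip_missing_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        if not (0 < self.read_length < self.genome_length):
            raise ValueError("need 0 < read_length < genome_length")
        if self.titv_bias < 0 or self.n_individuals < 1:
            raise ValueError("invalid titv_bias or n_individuals")


@dataclass
class ChipPanel:
    """Genotyping-array stand-in: truth genotypes at a subset of SNP sites.

    ``sites`` columns: chrom, pos (1-based), allele_a (reference allele),
    allele_b (alternate), call_rate. ``genotypes`` is individuals x sites
    with values 0/1/2 = alt-allele dosage and -1 = missing. Alleles are
    reported on the forward reference strand.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.sites["chrom"], self.sites["pos"].astype(int)))


@dataclass
class SyntheticCohort:
    """Everything the depth-titration experiment consumes.

    truth columns: chrom, pos (1-based), ref, alt, vclass (SNP/INS/DEL),
    af, known (bool: in the dbSNP-like list). ``genotypes`` is variants x
    individuals alt dosage; ``haplotypes`` is variants x 2*individuals.
    """

    genome: ReferenceGenome
    truth: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray
    known_sites: pd.DataFrame
    chip: ChipPanel
    config: SimConfig
    sample_names: list[str] = field(default_factory=list)

    def truth_snps(self) -> pd.DataFrame:
        return self.truth[self.truth["vclass"] == "SNP"]

    def truth_indels(self) -> pd.DataFrame:
        return self.truth[self.truth["vclass"] != "SNP"]


def simulate_genome(length: int, n_chromosomes: int = 1, seed=0) -> ReferenceGenome:
    """Uniform random A/C/G/T reference split into equal chromosomes."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    per = [length // n_chromosomes] * n_chromosomes
    per[-1] += length - sum(per)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    codes = [rng.integers(0, 4, size=n, dtype=np.uint8) for n in per]
    return ReferenceGenome(names, codes)


def _simulate_truth(genome: ReferenceGenome, cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for ci, codes in enumerate(genome.codes):
        L = len(codes)
        n_var = rng.binomial(L, cfg.variant_density)
        # leave headroom at the chromosome end for anchored deletions
        pos0 = np.sort(
            rng.choice(max(L - cfg.max_indel_len - 1, 1), size=min(n_var, L - cfg.max_indel_len - 1), replace=False)
        )
        is_snp = rng.random(pos0.size) < cfg.snp_fraction
        is_ins = ~is_snp & (rng.random(pos0.size) < 0.5)
        indel_len = rng.integers(1, cfg.max_indel_len + 1, size=pos0.size)
        # drop variants whose deletion span would overlap the next variant
        span = np.where(is_snp | is_ins, 0, indel_len)
        keep = np.ones(pos0.size, bool)
        last_end = -1
        for k in range(pos0.size):
            if pos0[k] <= last_end:
                keep[k] = False
                continue
            last_end = pos0[k] + span[k]
        pos0, is_snp, is_ins, indel_len = (
            pos0[keep],
            is_snp[keep],
            is_ins[keep],
            indel_len[keep],
        )
        ref_code = codes[pos0]
        # SNP alternate allele: transition with odds titv_bias : 1
        p_ti = cfg.titv_bias / (cfg.titv_bias + 1.0) if cfg.titv_bias > 0 else 0.0
        ti = rng.random(pos0.size) < p_ti
        tv_pick = rng.integers(0, 2, size=pos0.size)
        alt_code = np.where(
            ti,
            transition_partner(ref_code),
            # the two transversion partners of base b are b^1 and b^3
            ref_code ^ np.where(tv_pick == 0, 1, 3),
        ).astype(np.uint8)
        chrom = genome.chrom_names[ci]
        for k in range(pos0.size):
            p = int(pos0[k])
            if is_snp[k]:
                ref, alt, vc = "ACGT"[ref_code[k]], "ACGT"[alt_code[k]], "SNP"
            elif is_ins[k]:
                ins = decode_seq(rng.integers(0, 4, size=int(indel_len[k]), dtype=np.uint8))
                ref = "ACGT"[ref_code[k]]
                alt, vc = ref + ins, "INS"
            else:
                ref = decode_seq(codes[p : p + int(indel_len[k]) + 1])
                alt, vc = ref[0], "DEL"
            rows.append((chrom, p + 1, ref, alt, vc))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"])
    df["af"] = rng.beta(0.5, 0.5, size=len(df)) if len(df) else np.empty(0)
    return df


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full study scene from a config (deterministic in seed)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_genome, s_truth, s_geno, s_known, s_chip = root.spawn(5)
    genome = simulate_genome(config.genome_length, config.n_chromosomes, s_genome)
    rng_t = np.random.default_rng(s_truth)
    truth = _simulate_truth(genome, config, rng_t)
    n_var, n_ind = len(truth), config.n_individuals
    rng_g = np.random.default_rng(s_geno)
    haplotypes = (
        rng_g.random((n_var, 2 * n_ind)) < truth["af"].to_numpy()[:, None]
    ).astype(np.int8)
    genotypes = haplotypes[:, 0::2] + haplotypes[:, 1::2]

    rng_k = np.random.default_rng(s_known)
    known_mask = rng_k.random(n_var) < config.dbsnp_fraction
    truth = truth.assign(known=known_mask)
    known = truth.loc[known_mask, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    if config.known_extra > 0:
        # decoy entries absent from truth, to stress novel-rate logic
        taken = set(zip(truth["chrom"], truth["pos"]))
        decoys = []
        while len(decoys) < config.known_extra:
            ci = int(rng_k.integers(len(genome.chrom_names)))
            p = int(rng_k.integers(len(genome.codes[ci]))) + 1
            if (genome.chrom_names[ci], p) in taken:
                continue
            ref = "ACGT"[genome.codes[ci][p - 1]]
            alt = "ACGT"[(genome.codes[ci][p - 1] + 1) % 4]
            decoys.append((genome.chrom_names[ci], p, ref, alt))
            taken.add((genome.chrom_names[ci], p))
        known = pd.concat(
            [known, pd.DataFrame(decoys, columns=known.columns)], ignore_index=True
        ).sort_values(["chrom", "pos"], ignore_index=True)

    rng_c = np.random.default_rng(s_chip)
    snp_idx = np.flatnonzero((truth["vclass"] == "SNP").to_numpy())
    on_chip = snp_idx[rng_c.random(snp_idx.size) < config.chip_fraction]
    chip_geno = genotypes[on_chip].T.astype(np.int8).copy()
    missing = rng_c.random(chip_geno.shape) < config.chip_missing_rate
    chip_geno[missing] = -1
    call_rate = (
        (chip_geno >= 0).mean(axis=0) if chip_geno.size else np.empty(0)
    )
    chip_sites = truth.iloc[on_chip][["chrom", "pos", "ref", "alt"]].rename(
        columns={"ref": "allele_a", "alt": "allele_b"}
    )
    chip_sites = chip_sites.assign(call_rate=call_rate).reset_index(drop=True)
    chip = ChipPanel(chip_sites, chip_geno)

    return SyntheticCohort(
        genome=genome,
        truth=truth,
        genotypes=genotypes,
        haplotypes=haplotypes,
        known_sites=known,
        chip=chip,
        config=config,
        sample_names=[f"S{i + 1}" for i in range(n_ind)],
    )


def expected_pair_count(cfg: SimConfig) -> int:
    return int(round(cfg.mean_depth * cfg.genome_length / (2 * cfg.read_length)))


def simulate_reads(
    cohort: SyntheticCohort,
    individual: int,
    config: Optional[SimConfig] = None,
) -> ReadSet:
    """Simulate one individual's paired-end reads over the cohort genome.

    Fragment starts are uniform; each fragment is copied from one of the
    individual's two haplotypes; sequencing errors are injected at the
    configured rate with matching low qualities; a configured fraction of
    pairs are PCR duplicates of other pairs (sharing outer coordinates,
    with independent errors).
    """
    cfg = config or cohort.config
    if not (0 <= individual < cfg.n_individuals):
        raise ValueError(f"individual {individual} not in cohort")
    if cfg.mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    genome = cohort.genome
    rl = cfg.read_length
    n_pairs = expected_pair_count(cfg)
    if n_pairs == 0:
        return ReadSet.empty(genome.chrom_names, rl)
    ss = np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(1_000 + individual,)
    )
    rng = np.random.default_rng(ss)

    n_dup = int(round(cfg.duplicate_rate * n_pairs))
    n_orig = n_pairs - n_dup
    lengths = np.array([len(c) for c in genome.codes], dtype=np.int64)
    chrom_p = lengths / lengths.sum()
    chrom_of = rng.choice(len(lengths), size=n_orig, p=chrom_p)
    frag = np.clip(
        np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_orig)),
        rl,
        lengths[chrom_of],
    ).astype(np.int64)
    fstart = (rng.random(n_orig) * (lengths[chrom_of] - frag + 1)).astype(np.int64)
    hap = rng.integers(0, 2, size=n_orig)
    if n_dup > 0:
        src = rng.integers(0, n_orig, size=n_dup)
        chrom_of = np.concatenate([chrom_of, chrom_of[src]])
        frag = np.concatenate([frag, frag[src]])
        fstart = np.concatenate([fstart, fstart[src]])
        hap = np.concatenate([hap, hap[src]])

    # rows: pair k -> reads 2k (R1, forward) and 2k+1 (R2, reverse)
    n_reads = 2 * n_pairs
    chrom = np.repeat(chrom_of, 2).astype(np.int16)
    start = np.empty(n_reads, np.int64)
    start[0::2] = fstart
    start[1::2] = fstart + frag - rl
    is_rev = np.zeros(n_reads, bool)
    is_rev[1::2] = True
    mate = np.arange(n_reads, dtype=np.int64)
    mate[0::2] += 1
    mate[1::2] -= 1
    pair_id = np.repeat(np.arange(n_pairs, dtype=np.int64), 2)
    mapq = np.full(n_reads, cfg.mapq_high, np.uint8)
    low = rng.random(n_reads) < cfg.mapq_low_fraction
    mapq[low] = rng.integers(20, 51, size=int(low.sum()))
    qual = np.full((n_reads, rl), cfg.baseline_qual, np.uint8)

    # haplotype variant alleles carried by each read
    mm_parts, ind_parts = [], []
    hap_col = 2 * individual + hap  # per pair; reads share the pair haplotype
    for ci in range(len(genome.codes)):
        tv = cohort.truth
        vsel = np.flatnonzero((tv["chrom"] == genome.chrom_names[ci]).to_numpy())
        if vsel.size == 0:
            continue
        vpos0 = tv["pos"].to_numpy()[vsel] - 1
        rsel = np.flatnonzero(chrom == ci)
        lo = np.searchsorted(vpos0, start[rsel])
        hi = np.searchsorted(vpos0, start[rsel] + rl)
        counts = hi - lo
        reads_rep = np.repeat(rsel, counts)
        v_rep = vsel[
            np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
            if counts.sum()
            else np.empty(0, np.int64)
        ]
        if reads_rep.size == 0:
            continue
        carried = cohort.haplotypes[v_rep, hap_col[pair_id[reads_rep]]] == 1
        reads_rep, v_rep = reads_rep[carried], v_rep[carried]
        vc = tv["vclass"].to_numpy()[v_rep]
        snp = vc == "SNP"
        if snp.any():
            r, v = reads_rep[snp], v_rep[snp]
            off = (tv["pos"].to_numpy()[v] - 1 - start[r]).astype(np.int32)
            alt_code = np.array(
                ["ACGT".index(a) for a in tv["alt"].to_numpy()[v]], dtype=np.uint8
            )
            mm_parts.append((r, off, alt_code))
        if (~snp).any():
            r, v = reads_rep[~snp], v_rep[~snp]
            ind_parts.append(
                (
                    r,
                    np.full(r.size, ci, np.int16),
                    tv["pos"].to_numpy()[v].astype(np.int64),
                )
            )

    mm_read = np.concatenate([p[0] for p in mm_parts]) if mm_parts else np.empty(0, np.int64)
    mm_off = np.concatenate([p[1] for p in mm_parts]) if mm_parts else np.empty(0, np.int32)
    mm_base = np.concatenate([p[2] for p in mm_parts]) if mm_parts else np.empty(0, np.uint8)

    # sequencing errors on top of haplotype bases
    n_err = rng.binomial(n_reads * rl, cfg.base_error_rate)
    if n_err > 0:
        er = rng.integers(0, n_reads, size=n_err).astype(np.int64)
        eo = rng.integers(0, rl, size=n_err).astype(np.int32)
        # true base = haplotype base at that offset (reference unless a SNP mm sits there)
        true_code = np.empty(n_err, np.uint8)
        for k in range(n_err):
            ci = int(chrom[er[k]])
            true_code[k] = genome.codes[ci][start[er[k]] + eo[k]]
        if mm_read.size:
            key_mm = mm_read * rl + mm_off
            key_er = er * rl + eo
            order = np.argsort(key_mm, kind="stable")
            loc = np.searchsorted(key_mm[order], key_er)
            hit = (loc < key_mm.size) & (key_mm[order[np.minimum(loc, key_mm.size - 1)]] == key_er)
            true_code[hit] = mm_base[order[loc[hit]]]
        err_code = (true_code + rng.integers(1, 4, size=n_err)) % 4
        lowq = rng.random(n_err) < cfg.lowqual_error_fraction
        newq = np.where(lowq, rng.integers(2, 21, size=n_err), cfg.baseline_qual)
        qual[er, eo] = newq.astype(np.uint8)
        mm_read = np.concatenate([mm_read, er])
        mm_off = np.concatenate([mm_off, eo])
        mm_base = np.concatenate([mm_base, err_code.astype(np.uint8)])

    # dedupe mismatch records per (read, offset): later wins (errors override
    # haplotype alleles), then drop records that match the reference
    if mm_read.size:
        key = mm_read * rl + mm_off
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        last = np.r_[key_s[1:] != key_s[:-1], True]
        sel = order[last]
        mm_read, mm_off, mm_base = mm_read[sel], mm_off[sel], mm_base[sel]
        ref_code = np.empty(mm_read.size, np.uint8)
        for k in range(mm_read.size):
            ci = int(chrom[mm_read[k]])
            ref_code[k] = genome.codes[ci][start[mm_read[k]] + mm_off[k]]
        real = mm_base != ref_code
        mm_read, mm_off, mm_base = mm_read[real], mm_off[real], mm_base[real]
        order = np.lexsort((mm_off, mm_read))
        mm_read, mm_off, mm_base = mm_read[order], mm_off[order], mm_base[order]

    if ind_parts:
        ind_read = np.concatenate([p[0] for p in ind_parts])
        ind_chrom = np.concatenate([p[1] for p in ind_parts])
        ind_pos = np.concatenate([p[2] for p in ind_parts])
    else:
        ind_read = np.empty(0, np.int64)
        ind_chrom = np.empty(0, np.int16)
        ind_pos = np.empty(0, np.int64)

    return ReadSet(
        chrom_names=genome.chrom_names,
        chrom=chrom,
        start=start,
        length=np.full(n_reads, rl, np.int32),
        qoff=np.zeros(n_reads, np.int32),
        is_reverse=is_rev,
        mapq=mapq,
        is_dup=np.zeros(n_reads, bool),
        pair_id=pair_id,
        mate=mate,
        qual=qual,
        mm_read=mm_read,
        mm_off=mm_off,
        mm_base=mm_base,
        ind_read=ind_read,
        ind_chrom=ind_chrom,
        ind_pos=ind_pos,
    )
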