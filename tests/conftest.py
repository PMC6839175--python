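"""Shared fixtures: tiny hand-built read sets and the two expensive
session-scoped simulation runs (full-depth parameter-recovery scene and
the replicated 12-tier ladder runs) reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import depthdesign as dd
from depthdesign.genome import ReferenceGenome, encode_seq
from depthdesign.readops import ReadSet


def genome_from(seq: str, name: str = "chr1") -> ReferenceGenome:
    return ReferenceGenome([name], [encode_seq(seq)])


def build_readset(
    reads: list[dict], chrom_names: list[str] | None = None, genome=None
) -> ReadSet:
    """Construct a ReadSet from per-read dicts.

    Keys: start (0-based), quals (list or (q, length)), is_reverse, mapq,
    mate (absolute row index) or mate_offset (relative, e.g. +1/-1),
    mm (list of (offset, base_char)), chrom.
    """
    chrom_names = chrom_names or (genome.chrom_names if genome else ["chr1"])
    n = len(reads)
    lengths = []
    quals = []
    for r in reads:
        q = r.get("quals", (30, 100))
        if isinstance(q, tuple):
            q = [q[0]] * q[1]
        quals.append(list(q))
        lengths.append(len(q))
    row_len = max(lengths) if lengths else 0
    qual = np.zeros((n, row_len), np.uint8)
    for i, q in enumerate(quals):
        qual[i, : len(q)] = q
    mate = np.array(
        [
            i + r["mate_offset"] if "mate_offset" in r else r.get("mate", -1)
            for i, r in enumerate(reads)
        ],
        np.int64,
    )
    pair_id = np.zeros(n, np.int64)
    pid = 0
    assigned = np.full(n, -1, np.int64)
    for i in range(n):
        if assigned[i] >= 0:
            continue
        assigned[i] = pid
        if mate[i] >= 0:
            assigned[mate[i]] = pid
        pid += 1
    pair_id = assigned
    mm_read, mm_off, mm_base = [], [], []
    for i, r in enumerate(reads):
        for off, base in r.get("mm", []):
            mm_read.append(i)
            mm_off.append(off)
            mm_base.append("ACGT".index(base))
    order = np.lexsort((mm_off, mm_read)) if mm_read else np.empty(0, np.int64)
    return ReadSet(
        chrom_names=chrom_names,
        chrom=np.array([r.get("chrom", 0) for r in reads], np.int16),
        start=np.array([r["start"] for r in reads], np.int64),
        length=np.array(lengths, np.int32),
        qoff=np.zeros(n, np.int32),
        is_reverse=np.array([r.get("is_reverse", False) for r in reads], bool),
        mapq=np.array([r.get("mapq", 60) for r in reads], np.uint8),
        is_dup=np.array([r.get("is_dup", False) for r in reads], bool),
        pair_id=pair_id,
        mate=mate,
        qual=qual,
        mm_read=np.asarray(mm_read, np.int64)[order],
        mm_off=np.asarray(mm_off, np.int32)[order],
        mm_base=np.asarray(mm_base, np.uint8)[order],
    )


@pytest.fixture(scope="session")
def small_cohort() -> dd.SyntheticCohort:
    """200 kb, 3 individuals, default study conditions."""
    return dd.simulate_cohort(dd.SimConfig(genome_length=200_000, seed=42))


@pytest.fixture(scope="session")
def recovery_scene():
    """Full-depth parameter-recovery scene: 1 Mb, 3 samples at 20X.

    Returns (cohort, processed readsets, PASS multi calls, PASS single
    calls per sample).
    """
    cfg = dd.SimConfig(
        genome_length=1_000_000, mean_depth=20.0, titv_bias=2.2,
        dbsnp_fraction=0.85, seed=2024,
    )
    cohort = dd.simulate_cohort(cfg)
    readsets = {}
    for i, s in enumerate(cohort.sample_names):
        rs = dd.simulate_reads(cohort, i)
        rs = dd.trim_3prime(dd.qc_filter_reads(rs))
        readsets[s] = dd.mark_duplicates(rs)
    indels = cohort.truth_indels()[["chrom", "pos", "ref", "alt", "vclass"]]
    multi = dd.pass_only(
        dd.apply_hard_filter(dd.call_variants(readsets, cohort.genome, indel_sites=indels))
    )
    single = {
        s: dd.pass_only(
            dd.apply_hard_filter(
                dd.call_variants({s: readsets[s]}, cohort.genome, indel_sites=indels)
            )
        )
        for s in cohort.sample_names
    }
    return cohort, readsets, multi, single


@pytest.fixture(scope="session")
def ladder_reports():
    """Five replicate full 12-tier titrations (1 Mb x 3 samples, both modes)."""
    reports = []
    for seed in range(5):
        cohort = dd.simulate_cohort(
            dd.SimConfig(genome_length=1_000_000, seed=100 + seed)
        )
        reports.append(dd.run_depth_series(cohort, seed=seed))
    return reports
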