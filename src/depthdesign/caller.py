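"""Pileup-based diploid genotype caller (UnifiedGenotyper-style).

Model
-----
Per sample and site, the likelihood of a diploid genotype g = {a1, a2}
over observed bases b with per-base error probability eps is

    L(g) = prod_b [ 1/2 P(b|a1) + 1/2 P(b|a2) ],
    P(b|a) = 1 - eps  if b == a  else  eps / 3,

with eps derived from the base quality capped by the read's mapping
quality and by Q40. Sites are then scored with an exact posterior over
the alternate allele count AC among the 2N sampled chromosomes: the
prior is P(AC=i) = theta/i (i >= 1) with the remaining mass on AC=0, and
P(D|AC=i) is computed exactly by convolving per-sample weighted
likelihoods z_s(j) = L_s(j) * C(2,j) across samples and dividing by
C(2N, i). Site quality is -10 log10 P(AC=0 | D); a variant is emitted
when it reaches the emission confidence. Single-sample calling is the
N=1 special case of the same machinery.

Annotations follow the hard-filter vocabulary: QD (quality over the
depth of alt-carrying samples), FS (phred-scaled two-sided Fisher exact
p of the strand x allele table), MQ (root-mean-square mapping quality),
and MQRankSum / ReadPosRankSum (normal-approximation Mann-Whitney z of
alt vs ref reads on mapping quality and distance to the nearer read
end; absent when either group is empty).

Only biallelic sites are called; at multiallelic pileups the alternate
with the highest summed base quality is taken. Indels are genotyped by
the same likelihood machinery on gapped-vs-ungapped read support at
registered sites (the simulator tags indel-supporting reads); de novo
gap discovery is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata

from .genome import ReferenceGenome
from .readops import ReadSet

QUAL_CAP_Q = 40  # error-probability floor 1e-4
_GKEY_SHIFT = np.int64(1) << np.int64(40)


@dataclass
class SampleEvidence:
    """Stacked per-read observations of one sample at one position."""

    bases: np.ndarray  # '<U1'
    base_qual: np.ndarray  # int
    map_qual: np.ndarray  # int
    is_reverse: np.ndarray  # bool
    offset_from_read_end: np.ndarray  # int, distance to nearer end

    @property
    def depth(self) -> int:
        return int(len(self.bases))


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    ref: str
    samples: dict[str, SampleEvidence] = field(default_factory=dict)


@dataclass
class GenotypeLikelihoods:
    chrom: str
    pos: int
    sample: str
    gl: np.ndarray  # log10 likelihoods for (hom-ref, het, hom-alt)

    def pl(self) -> np.ndarray:
        return np.round(-10.0 * (self.gl - self.gl.max())).astype(int)


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    qual: float
    mode: str
    genotypes: dict[str, int]  # sample -> alt dosage 0/1/2
    pls: dict[str, np.ndarray]
    depths: dict[str, int] = field(default_factory=dict)
    annotations: dict[str, float] = field(default_factory=dict)
    filter_status: str | list[str] = "."


# --------------------------------------------------------------------------
# pileup


def pileup(
    rs: ReadSet, genome: ReferenceGenome, sample: str = "S1"
) -> Iterator[PileupColumn]:
    """Yield one column per covered position (duplicates excluded)."""
    for ci, codes in enumerate(genome.codes):
        cols: dict[int, list] = {}
        for i in range(rs.n_reads):
            if rs.is_dup[i] or rs.chrom[i] != ci or rs.length[i] <= 0:
                continue
            if rs.end[i] > len(codes):
                raise ValueError("read overruns chromosome end")
            bases = rs.bases(i, genome)
            quals = rs.window_qual(i)
            for j in range(int(rs.length[i])):
                p0 = int(rs.start[i]) + j
                cols.setdefault(p0, []).append(
                    (
                        "ACGT"[bases[j]],
                        int(quals[j]),
                        int(rs.mapq[i]),
                        bool(rs.is_reverse[i]),
                        min(j, int(rs.length[i]) - 1 - j),
                    )
                )
        for p0 in sorted(cols):
            rows = cols[p0]
            ev = SampleEvidence(
                bases=np.array([r[0] for r in rows]),
                base_qual=np.array([r[1] for r in rows]),
                map_qual=np.array([r[2] for r in rows]),
                is_reverse=np.array([r[3] for r in rows]),
                offset_from_read_end=np.array([r[4] for r in rows]),
            )
            yield PileupColumn(
                chrom=genome.chrom_names[ci],
                pos=p0 + 1,
                ref="ACGT"[codes[p0]],
                samples={sample: ev},
            )


# --------------------------------------------------------------------------
# genotype likelihoods


def _eps_from_quals(base_qual, map_qual) -> np.ndarray:
    q = np.minimum(np.minimum(base_qual, map_qual), QUAL_CAP_Q)
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def genotype_likelihood(
    column: PileupColumn, sample: str, ref: str, alt: str
) -> GenotypeLikelihoods:
    """log10 likelihoods of (ref/ref, ref/alt, alt/alt) for one sample.

    Bases matching neither allele contribute equally to every genotype
    and are dropped. Zero informative reads give flat likelihoods.
    """
    ev = column.samples.get(sample)
    gl = np.zeros(3)
    if ev is not None and ev.depth:
        eps = _eps_from_quals(ev.base_qual, ev.map_qual)
        is_ref = ev.bases == ref
        is_alt = ev.bases == alt
        gl = _gl_from_rows(eps, is_ref, is_alt)
    return GenotypeLikelihoods(column.chrom, column.pos, sample, gl)


def _gl_from_rows(eps: np.ndarray, is_ref: np.ndarray, is_alt: np.ndarray) -> np.ndarray:
    """Sum log10 per-read terms into the 3-genotype likelihood vector."""
    gl = np.zeros(3)
    match = np.log10(1.0 - eps)
    miss = np.log10(eps / 3.0)
    het = np.log10(0.5 * (1.0 - eps) + 0.5 * eps / 3.0)
    gl[0] = match[is_ref].sum() + miss[is_alt].sum()
    gl[2] = miss[is_ref].sum() + match[is_alt].sum()
    gl[1] = het[is_ref | is_alt].sum()
    return gl


# --------------------------------------------------------------------------
# allele-count posterior


def ac_prior_log10(n_samples: int, theta: float) -> np.ndarray:
    """log10 P(AC=i), i = 0..2N, under the theta/i heterozygosity prior."""
    two_n = 2 * n_samples
    if theta <= 0:
        raise ValueError("theta must be positive")
    h = sum(1.0 / i for i in range(1, two_n + 1))
    if theta * h >= 1.0:
        raise ValueError("theta too large: prior mass on AC=0 would be <= 0")
    p = np.empty(two_n + 1)
    p[0] = 1.0 - theta * h
    p[1:] = theta / np.arange(1, two_n + 1)
    return np.log10(p)


def _ac_data_log10(gl_log10: np.ndarray) -> np.ndarray:
    """log10 P(D|AC=i) (up to one common constant) for (N,3) log10 GLs.

    Exact dynamic programme: convolve z_s(j) = Lnorm_s(j)*C(2,j) across
    samples, divide by C(2N, i). The AC=0 coefficient is recomputed
    analytically in log space so deep-coverage sites cannot underflow it.
    """
    gl = np.asarray(gl_log10, dtype=float).reshape(-1, 3)
    n = gl.shape[0]
    norm = gl - gl.max(axis=1, keepdims=True)
    z = (10.0 ** norm) * np.array([1.0, 2.0, 1.0])
    c = np.ones(1)
    for s in range(n):
        c = np.convolve(c, z[s])
    denom = np.array([math.comb(2 * n, i) for i in range(2 * n + 1)], dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log10(c) - np.log10(denom)
    out[0] = norm[:, 0].sum()
    return out


def ac_likelihoods(gl_log10: np.ndarray) -> np.ndarray:
    """P(D|AC=i) for normalized per-sample GLs, on the linear scale."""
    lg = _ac_data_log10(gl_log10)
    return 10.0 ** lg


def _genotypes_from_posterior(
    gl_log10: np.ndarray, post: np.ndarray
) -> np.ndarray:
    """Per-sample MAP genotypes under an HWE prior at the posterior-mean AF."""
    n = gl_log10.shape[0]
    q = float((np.arange(post.size) * post).sum() / (2 * n))
    with np.errstate(divide="ignore"):
        prior = np.log10(
            np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        )
    return np.argmax(gl_log10 + prior, axis=1)


def call_site_multi(
    gls: "list[GenotypeLikelihoods] | np.ndarray",
    theta: float = 1e-3,
    emit_conf: float = 30.0,
    *,
    chrom: str = "chr1",
    pos: int = 1,
    ref: str = "N",
    alt: str = "N",
    vclass: str = "SNP",
    samples: Optional[list[str]] = None,
) -> Optional[VariantCall]:
    """Joint call across samples from their genotype likelihoods.

    Returns the emitted VariantCall, or None when the site does not reach
    the emission confidence.
    """
    if isinstance(gls, np.ndarray):
        gl = gls.reshape(-1, 3).astype(float)
        names = samples or [f"S{i+1}" for i in range(gl.shape[0])]
    else:
        gl = np.stack([g.gl for g in gls]).astype(float)
        names = samples or [g.sample for g in gls]
        chrom, pos = gls[0].chrom, gls[0].pos
    prior = ac_prior_log10(gl.shape[0], theta)
    data = _ac_data_log10(gl)
    joint = prior + data
    m = joint.max()
    logdenom = m + np.log10((10.0 ** (joint - m)).sum())
    log_post0 = joint[0] - logdenom
    qual = -10.0 * log_post0
    if qual < emit_conf:
        return None
    post = 10.0 ** (joint - logdenom)
    gts = _genotypes_from_posterior(gl, post)
    pls = {
        s: np.round(-10.0 * (gl[i] - gl[i].max())).astype(int)
        for i, s in enumerate(names)
    }
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vclass=vclass,
        qual=float(qual),
        mode="multi" if gl.shape[0] > 1 else "single",
        genotypes={s: int(g) for s, g in zip(names, gts)},
        pls=pls,
    )


def call_site_single(
    gls: GenotypeLikelihoods, theta: float = 1e-3, emit_conf: float = 30.0, **kw
) -> Optional[VariantCall]:
    """Single-sample calling: call_site_multi with N = 1."""
    return call_site_multi([gls], theta=theta, emit_conf=emit_conf, **kw)


# --------------------------------------------------------------------------
# annotations


def fisher_strand(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """FS: -10 log10 of the two-sided Fisher exact p for strand imbalance."""
    table = [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]
    p = fisher_exact(table, alternative="two-sided")[1]
    return float(max(-10.0 * np.log10(max(p, 1e-300)), 0.0))


def rms_mapping_quality(map_quals) -> float:
    mq = np.asarray(map_quals, dtype=float)
    if mq.size == 0:
        return float("nan")
    return float(np.sqrt((mq**2).mean()))


def rank_sum_z(alt_values, ref_values) -> Optional[float]:
    """Mann-Whitney z (normal approximation) of alt vs ref values.

    Mid-ranks for ties, tie-corrected variance, continuity correction
    0.5 toward zero; negative when alt values run lower than ref.
    Absent (None) when either group is empty.
    """
    a = np.asarray(alt_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    n1, n2 = a.size, r.size
    if n1 == 0 or n2 == 0:
        return None
    combined = np.concatenate([a, r])
    ranks = rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie)
    if var <= 0:
        return 0.0
    diff = u1 - mu
    shrunk = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    return float(shrunk / math.sqrt(var))


def annotate(call: VariantCall, columns: Mapping[str, PileupColumn]) -> VariantCall:
    """Attach QD/FS/MQ/rank-sum annotations from per-sample pileups."""
    eps_rows, cls_rows, mq_rows, rev_rows, off_rows, samp = [], [], [], [], [], []
    for s, col in columns.items():
        ev = col.samples.get(s)
        if ev is None:
            continue
        cls = np.where(ev.bases == call.alt, 1, np.where(ev.bases == call.ref, 0, 2))
        mq_rows.append(ev.map_qual)
        rev_rows.append(ev.is_reverse)
        off_rows.append(ev.offset_from_read_end)
        cls_rows.append(cls)
        samp.extend([s] * ev.depth)
    if not cls_rows:
        return call
    cls = np.concatenate(cls_rows)
    mq = np.concatenate(mq_rows)
    rev = np.concatenate(rev_rows)
    off = np.concatenate(off_rows)
    samp = np.array(samp)
    call.annotations.update(
        _annotations_from_rows(call, cls, mq, rev, off, samp)
    )
    return call


def _annotations_from_rows(call, cls, mq, rev, off, samp) -> dict[str, float]:
    ann: dict[str, float] = {}
    is_ref, is_alt = cls == 0, cls == 1
    ann["MQ"] = rms_mapping_quality(mq)
    ann["FS"] = fisher_strand(
        int((is_ref & ~rev).sum()),
        int((is_ref & rev).sum()),
        int((is_alt & ~rev).sum()),
        int((is_alt & rev).sum()),
    )
    carriers = {s for s, g in call.genotypes.items() if g > 0}
    depth_carriers = int(np.isin(samp, list(carriers)).sum()) if carriers else 0
    if depth_carriers > 0:
        ann["QD"] = call.qual / depth_carriers
    z = rank_sum_z(mq[is_alt], mq[is_ref])
    if z is not None:
        ann["MQRankSum"] = z
    z = rank_sum_z(off[is_alt], off[is_ref])
    if z is not None:
        ann["ReadPosRankSum"] = z
    call.depths = {
        s: int((samp == s).sum()) for s in dict.fromkeys(samp.tolist())
    } or call.depths
    return ann


# --------------------------------------------------------------------------
# batch calling over ReadSets


def _gkeys(chrom_idx, pos0) -> np.ndarray:
    return np.asarray(chrom_idx, np.int64) * _GKEY_SHIFT + np.asarray(pos0, np.int64)


def call_variants(
    readsets: Mapping[str, ReadSet],
    genome: ReferenceGenome,
    *,
    theta: float = 1e-3,
    emit_conf: float = 30.0,
    indel_sites: Optional[pd.DataFrame] = None,
    min_alt_reads: int = 2,
) -> pd.DataFrame:
    """Call every candidate site jointly across the given samples.

    Pass a single-entry mapping for single-sample calling. Candidate SNP
    sites are positions with >= min_alt_reads non-reference bases across
    the calling unit (a site reaching emission confidence 30 always has
    at least two alt reads under the Q40 error floor, so the prefilter is
    lossless); candidate indel sites are registered sites (chrom, pos,
    ref, alt) with tagged gapped support. Returns one row per emitted
    variant with annotations and per-sample genotype fields; the
    ``filter`` column is left unset ('.') for the hard filter to fill.
    """
    names = list(readsets)
    n = len(names)
    prior = ac_prior_log10(n, theta)

    # per-sample preprocessed views
    active, starts_sorted, order_by_start, ends, mm = {}, {}, {}, {}, {}
    ind_support: dict[str, dict[int, np.ndarray]] = {}
    for s in names:
        rs = readsets[s]
        act = (~rs.is_dup) & (rs.length > 0)
        active[s] = act
        order = np.argsort(rs.start, kind="stable")
        order = order[act[order]]
        order_by_start[s] = order
        starts_sorted[s] = rs.start[order]
        ends[s] = rs.end
        r, gpos, base, q = rs.live_mismatches()
        keep = act[r]
        r, gpos, base, q = r[keep], gpos[keep], base[keep], q[keep]
        qcap = np.minimum(np.minimum(q, rs.mapq[r]), QUAL_CAP_Q)
        gk = _gkeys(rs.chrom[r], gpos)
        o = np.argsort(gk, kind="stable")
        mm[s] = (gk[o], r[o], base[o], qcap[o].astype(np.int16))
        sup: dict[int, np.ndarray] = {}
        if rs.ind_read.size:
            keep_i = act[rs.ind_read]
            gk_i = _gkeys(rs.ind_chrom[keep_i], rs.ind_pos[keep_i] - 1)
            for k, rd in zip(gk_i, rs.ind_read[keep_i]):
                sup.setdefault(int(k), []).append(int(rd))
            sup = {k: np.array(v, np.int64) for k, v in sup.items()}
        ind_support[s] = sup

    # candidate SNP sites: pooled non-reference evidence
    all_gk = np.concatenate([mm[s][0] for s in names]) if names else np.empty(0, np.int64)
    uk, counts = np.unique(all_gk, return_counts=True)
    snp_keys = uk[counts >= min_alt_reads]

    # chosen alternate per SNP candidate: highest summed capped quality
    alt_of: dict[int, int] = {}
    if snp_keys.size:
        gk = all_gk
        base = np.concatenate([mm[s][2] for s in names])
        qc = np.concatenate([mm[s][3] for s in names]).astype(np.int64)
        sel = np.isin(gk, snp_keys)
        gk, base, qc = gk[sel], base[sel], qc[sel]
        comb = gk * 4 + base
        uu, inv = np.unique(comb, return_inverse=True)
        sums = np.bincount(inv, weights=qc)
        best: dict[int, tuple[float, int]] = {}
        for u, tot in zip(uu, sums):
            k, b = int(u // 4), int(u % 4)
            if k not in best or tot > best[k][0]:
                best[k] = (tot, b)
        alt_of = {k: b for k, (_, b) in best.items()}

    # registered indel sites with tagged support in the unit
    indel_meta: dict[int, tuple[str, str, str]] = {}
    if indel_sites is not None and len(indel_sites):
        for _, row in indel_sites.iterrows():
            ci = genome.chrom_index(row["chrom"])
            k = int(_gkeys(ci, row["pos"] - 1))
            nsup = sum(ind_support[s].get(k, np.empty(0)).size for s in names)
            if nsup >= min_alt_reads:
                indel_meta[k] = (row["ref"], row["alt"], row["vclass"])

    site_keys = sorted(set(int(k) for k in snp_keys if int(k) not in indel_meta) | set(indel_meta))
    if not site_keys:
        return _empty_calls_frame(names)
    site_keys = np.array(site_keys, np.int64)
    S = site_keys.size
    site_index = {int(k): i for i, k in enumerate(site_keys)}

    # evidence assembly
    ev_site, ev_samp, ev_cls, ev_q, ev_mq, ev_rev, ev_off = (
        [], [], [], [], [], [], []
    )
    max_len = max(
        (int(readsets[s].length.max()) if readsets[s].n_reads else 0) for s in names
    )
    for si, key in enumerate(site_keys):
        ci = int(key // _GKEY_SHIFT)
        p0 = int(key % _GKEY_SHIFT)
        is_indel = int(key) in indel_meta
        ref_code = int(genome.codes[ci][p0])
        for sj, s in enumerate(names):
            rs = readsets[s]
            ss = starts_sorted[s]
            lo = np.searchsorted(ss, p0 - max_len + 1 if max_len else p0, "left")
            hi = np.searchsorted(ss, p0, "right")
            cand = order_by_start[s][lo:hi]
            cand = cand[(ends[s][cand] > p0) & (rs.chrom[cand] == ci)]
            if cand.size == 0:
                continue
            j = p0 - rs.start[cand]
            bq = rs.qual[cand, rs.qoff[cand] + j]
            qcap = np.minimum(np.minimum(bq, rs.mapq[cand]), QUAL_CAP_Q)
            if is_indel:
                supp = ind_support[s].get(int(key), np.empty(0, np.int64))
                cls = np.where(np.isin(cand, supp), 1, 0)
            else:
                gk_mm, r_mm, b_mm, _ = mm[s]
                a = np.searchsorted(gk_mm, key, "left")
                b = np.searchsorted(gk_mm, key, "right")
                base_of = dict(zip(r_mm[a:b].tolist(), b_mm[a:b].tolist()))
                alt_code = alt_of.get(int(key), -1)
                cls = np.array(
                    [
                        1 if base_of.get(int(c), ref_code) == alt_code
                        else (0 if int(c) not in base_of else 2)
                        for c in cand
                    ],
                    np.int8,
                )
            ev_site.append(np.full(cand.size, si, np.int64))
            ev_samp.append(np.full(cand.size, sj, np.int16))
            ev_cls.append(cls.astype(np.int8))
            ev_q.append(qcap.astype(np.int16))
            ev_mq.append(rs.mapq[cand].astype(np.int16))
            ev_rev.append(rs.is_reverse[cand])
            ev_off.append(np.minimum(j, rs.length[cand] - 1 - j).astype(np.int32))
    if not ev_site:
        return _empty_calls_frame(names)
    ev_site = np.concatenate(ev_site)
    ev_samp = np.concatenate(ev_samp)
    ev_cls = np.concatenate(ev_cls)
    ev_q = np.concatenate(ev_q)
    ev_mq = np.concatenate(ev_mq)
    ev_rev = np.concatenate(ev_rev)
    ev_off = np.concatenate(ev_off)

    # genotype likelihoods, vectorized over all (site, sample) pairs
    gl = np.zeros((S, n, 3))
    informative = ev_cls < 2
    eps = 10.0 ** (-ev_q[informative].astype(float) / 10.0)
    si_, sj_ = ev_site[informative], ev_samp[informative].astype(np.int64)
    is_alt = ev_cls[informative] == 1
    l_match = np.log10(1.0 - eps)
    l_miss = np.log10(eps / 3.0)
    l_het = np.log10(0.5 * (1.0 - eps) + 0.5 * eps / 3.0)
    np.add.at(gl, (si_, sj_, 0), np.where(is_alt, l_miss, l_match))
    np.add.at(gl, (si_, sj_, 2), np.where(is_alt, l_match, l_miss))
    np.add.at(gl, (si_, sj_, 1), l_het)

    # exact AC posterior per site
    norm = gl - gl.max(axis=2, keepdims=True)
    z = (10.0 ** norm) * np.array([1.0, 2.0, 1.0])
    c = np.ones((S, 1))
    for sj in range(n):
        k = c.shape[1]
        cnew = np.zeros((S, k + 2))
        for jj in range(3):
            cnew[:, jj : jj + k] += c * z[:, sj, jj][:, None]
        c = cnew
    denom = np.array([math.comb(2 * n, i) for i in range(2 * n + 1)], dtype=float)
    with np.errstate(divide="ignore"):
        log_data = np.log10(c) - np.log10(denom)
    log_data[:, 0] = norm[:, :, 0].sum(axis=1)
    joint = prior + log_data
    m = joint.max(axis=1, keepdims=True)
    logdenom = m[:, 0] + np.log10((10.0 ** (joint - m)).sum(axis=1))
    qual = -10.0 * (joint[:, 0] - logdenom)
    emit = qual >= emit_conf
    post = 10.0 ** (joint - logdenom[:, None])
    qbar = (post * np.arange(2 * n + 1)).sum(axis=1) / (2 * n)
    with np.errstate(divide="ignore"):
        g_prior = np.log10(
            np.stack([(1 - qbar) ** 2, 2 * qbar * (1 - qbar), qbar**2], axis=1)
        )
    gts = np.argmax(gl + g_prior[:, None, :], axis=2)

    # assemble emitted records with annotations
    order = np.argsort(ev_site, kind="stable")
    ev_sorted = order
    bounds = np.searchsorted(ev_site[order], np.arange(S + 1))
    rows = []
    mode = "multi" if n > 1 else "single"
    for si in np.flatnonzero(emit):
        key = int(site_keys[si])
        ci, p0 = key // int(_GKEY_SHIFT), key % int(_GKEY_SHIFT)
        if key in indel_meta:
            ref, alt, vclass = indel_meta[key]
        else:
            ref = "ACGT"[int(genome.codes[ci][p0])]
            alt = "ACGT"[alt_of[key]]
            vclass = "SNP"
        sel = ev_sorted[bounds[si] : bounds[si + 1]]
        cls, mqv, rev, off, samp = (
            ev_cls[sel], ev_mq[sel], ev_rev[sel], ev_off[sel], ev_samp[sel],
        )
        is_ref, is_alt_r = cls == 0, cls == 1
        gt = gts[si]
        rec = {
            "chrom": genome.chrom_names[ci],
            "pos": int(p0) + 1,
            "ref": ref,
            "alt": alt,
            "vclass": vclass,
            "qual": float(qual[si]),
            "mode": mode,
            "AC": int(gt.sum()),
            "AN": 2 * n,
            "DP": int(sel.size),
            "MQ": rms_mapping_quality(mqv),
            "FS": fisher_strand(
                int((is_ref & ~rev).sum()),
                int((is_ref & rev).sum()),
                int((is_alt_r & ~rev).sum()),
                int((is_alt_r & rev).sum()),
            ),
            "filter": ".",
        }
        carrier_depth = int(np.isin(samp, np.flatnonzero(gt > 0)).sum())
        rec["QD"] = float(qual[si]) / carrier_depth if carrier_depth else np.nan
        zv = rank_sum_z(mqv[is_alt_r], mqv[is_ref])
        rec["MQRankSum"] = np.nan if zv is None else zv
        zv = rank_sum_z(off[is_alt_r], off[is_ref])
        rec["ReadPosRankSum"] = np.nan if zv is None else zv
        for sj, s in enumerate(names):
            rec[f"GT_{s}"] = int(gt[sj])
            rec[f"DP_{s}"] = int((samp == sj).sum())
            pl = np.round(-10.0 * (gl[si, sj] - gl[si, sj].max())).astype(int)
            rec[f"PL_{s}"] = ",".join(str(int(x)) for x in pl)
        rows.append(rec)
    df = pd.DataFrame(rows, columns=_calls_columns(names))
    if len(df):
        df = df.sort_values(["chrom", "pos"], ignore_index=True)
    df.attrs["samples"] = names
    return df


def _calls_columns(names: list[str]) -> list[str]:
    cols = [
        "chrom", "pos", "ref", "alt", "vclass", "qual", "mode",
        "AC", "AN", "DP", "MQ", "FS", "QD", "MQRankSum", "ReadPosRankSum",
        "filter",
    ]
    for s in names:
        cols += [f"GT_{s}", f"DP_{s}", f"PL_{s}"]
    return cols


def _empty_calls_frame(names: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(columns=_calls_columns(names))
    df.attrs["samples"] = names
    return df
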