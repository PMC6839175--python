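"""Read-level processing ahead of variant calling.

The stages mirror a standard resequencing pipeline: base-quality QC
(drop reads with too many low-quality bases, pair-consistently), 3'
trimming, PCR-duplicate marking on fragment outer coordinates, and
mate-pair-consistent random downsampling arranged as a *nested* ladder
of depth tiers, so that every lower-depth tier is a subset of the next
higher one and depth-response curves are monotone by construction.

``ReadSet`` is a struct-of-arrays container. Read bases are stored as
sparse mismatches against the reference (most simulated bases equal the
reference); base qualities are a dense uint8 matrix. Each read exposes a
valid window ``[qoff, qoff+length)`` into its original quality row so
that 3' trimming is an O(1) window adjustment. Rows are kept in mate
pairs via reciprocal ``mate`` indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .genome import ReferenceGenome


@dataclass
class ReadSet:
    """Placed, paired, quality-annotated reads (SAM-compatible semantics).

    Coordinates: ``start`` is the 0-based leftmost aligned position of the
    current valid window; genome position of window base j is start + j.
    Mismatch records (mm_*) are offsets into the *original* quality row;
    a record is live only while ``qoff <= mm_off < qoff + length``.
    """

    chrom_names: list[str]
    chrom: np.ndarray  # int16 per read
    start: np.ndarray  # int64, 0-based
    length: np.ndarray  # int32 current aligned length
    qoff: np.ndarray  # int32 window start inside the quality row
    is_reverse: np.ndarray  # bool
    mapq: np.ndarray  # uint8
    is_dup: np.ndarray  # bool
    pair_id: np.ndarray  # int64, shared by mates
    mate: np.ndarray  # int64 row index of mate, -1 if unpaired
    qual: np.ndarray  # uint8 (n_reads, row_len)
    # sparse mismatches vs the reference, sorted by (read, offset)
    mm_read: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mm_off: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    mm_base: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint8))
    # indel-support tags: read row -> truth indel site (chrom, 1-based pos)
    ind_read: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ind_chrom: np.ndarray = field(default_factory=lambda: np.empty(0, np.int16))
    ind_pos: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_reads(self) -> int:
        return int(self.start.shape[0])

    @property
    def end(self) -> np.ndarray:
        """0-based exclusive right ends."""
        return self.start + self.length

    def read_name(self, i: int) -> str:
        suffix = "/2" if self.mate[i] >= 0 and self.mate[i] < i else "/1"
        return f"p{int(self.pair_id[i])}{suffix}"

    def pair_name(self, i: int) -> str:
        return f"p{int(self.pair_id[i])}"

    @classmethod
    def empty(cls, chrom_names: list[str], row_len: int = 0) -> "ReadSet":
        z = np.empty(0, np.int64)
        return cls(
            chrom_names=chrom_names,
            chrom=np.empty(0, np.int16),
            start=z.copy(),
            length=np.empty(0, np.int32),
            qoff=np.empty(0, np.int32),
            is_reverse=np.empty(0, bool),
            mapq=np.empty(0, np.uint8),
            is_dup=np.empty(0, bool),
            pair_id=z.copy(),
            mate=z.copy(),
            qual=np.empty((0, row_len), np.uint8),
        )

    # ---- window accessors -------------------------------------------------

    def window_qual(self, i: int) -> np.ndarray:
        return self.qual[i, self.qoff[i] : self.qoff[i] + self.length[i]]

    def valid_mask(self) -> np.ndarray:
        """Boolean (n_reads, row_len) marking in-window cells."""
        cols = np.arange(self.qual.shape[1])
        lo = self.qoff[:, None]
        return (cols >= lo) & (cols < lo + self.length[:, None])

    def summed_base_quality(self) -> np.ndarray:
        q = np.where(self.valid_mask(), self.qual, 0)
        return q.sum(axis=1, dtype=np.int64)

    def live_mismatches(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(read, genome_pos0, base_code, qual) for in-window mismatches."""
        if self.mm_read.size == 0:
            e = np.empty(0, np.int64)
            return e, e.copy(), np.empty(0, np.uint8), np.empty(0, np.uint8)
        r = self.mm_read
        live = (self.mm_off >= self.qoff[r]) & (self.mm_off < self.qoff[r] + self.length[r])
        r = r[live]
        off = self.mm_off[live]
        gpos = self.start[r] + (off - self.qoff[r])
        return r, gpos, self.mm_base[live], self.qual[r, off]

    def bases(self, i: int, genome: ReferenceGenome) -> np.ndarray:
        """Base codes of read i's valid window, reconstructed vs reference."""
        ci = int(self.chrom[i])
        codes = genome.codes[ci][self.start[i] : self.start[i] + self.length[i]].copy()
        sel = self.mm_read == i
        if sel.any():
            off = self.mm_off[sel]
            live = (off >= self.qoff[i]) & (off < self.qoff[i] + self.length[i])
            codes[off[live] - self.qoff[i]] = self.mm_base[sel][live]
        return codes

    # ---- structural ops ---------------------------------------------------

    def take(self, indices: np.ndarray) -> "ReadSet":
        """Subset to the given row indices (mates must be taken together)."""
        indices = np.asarray(indices, dtype=np.int64)
        inv = np.full(self.n_reads, -1, dtype=np.int64)
        inv[indices] = np.arange(indices.size)
        new_mate = np.where(self.mate[indices] >= 0, inv[self.mate[indices]], -1)
        if ((self.mate[indices] >= 0) & (new_mate < 0)).any():
            raise ValueError("take() would orphan a mate; subset pairs together")
        keep_mm = inv[self.mm_read] >= 0 if self.mm_read.size else np.empty(0, bool)
        keep_ind = inv[self.ind_read] >= 0 if self.ind_read.size else np.empty(0, bool)
        return ReadSet(
            chrom_names=self.chrom_names,
            chrom=self.chrom[indices],
            start=self.start[indices].copy(),
            length=self.length[indices].copy(),
            qoff=self.qoff[indices].copy(),
            is_reverse=self.is_reverse[indices].copy(),
            mapq=self.mapq[indices].copy(),
            is_dup=self.is_dup[indices].copy(),
            pair_id=self.pair_id[indices].copy(),
            mate=new_mate,
            qual=self.qual[indices].copy(),
            mm_read=inv[self.mm_read[keep_mm]] if self.mm_read.size else self.mm_read,
            mm_off=self.mm_off[keep_mm],
            mm_base=self.mm_base[keep_mm],
            ind_read=inv[self.ind_read[keep_ind]] if self.ind_read.size else self.ind_read,
            ind_chrom=self.ind_chrom[keep_ind],
            ind_pos=self.ind_pos[keep_ind],
        )

    def check_pairing(self) -> None:
        """Raise if mate linkage is not reciprocal."""
        m = self.mate
        paired = m >= 0
        if paired.any():
            idx = np.flatnonzero(paired)
            if not (self.mate[m[idx]] == idx).all():
                raise AssertionError("non-reciprocal mate linkage")
            if not (self.pair_id[m[idx]] == self.pair_id[idx]).all():
                raise AssertionError("mates disagree on pair_id")


@dataclass
class DepthTier:
    """One rung of the downsampling ladder."""

    proportion: float
    nominal_depth: float | None
    read_subset: ReadSet


def _drop_with_mates(rs: ReadSet, fail: np.ndarray) -> ReadSet:
    """Remove failing reads and, for paired reads, their mates too."""
    drop = fail.copy()
    paired = rs.mate >= 0
    drop[paired] |= fail[rs.mate[paired]]
    return rs.take(np.flatnonzero(~drop))


def qc_filter_reads(
    rs: ReadSet, max_lowq_fraction: float = 0.30, lowq_threshold: int = 20
) -> ReadSet:
    """Drop reads whose low-quality fraction exceeds the threshold.

    A read fails iff (#bases with Q <= lowq_threshold)/length is *strictly*
    greater than max_lowq_fraction; a failing read takes its mate with it.
    """
    if not (0.0 <= max_lowq_fraction <= 1.0) or lowq_threshold < 0:
        raise ValueError("invalid QC thresholds")
    if rs.n_reads == 0:
        return rs
    lowq = ((rs.qual <= lowq_threshold) & rs.valid_mask()).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(rs.length > 0, lowq / np.maximum(rs.length, 1), 0.0)
    return _drop_with_mates(rs, frac > max_lowq_fraction)


def trim_3prime(rs: ReadSet, quality_threshold: int = 20) -> ReadSet:
    """Trim trailing sub-threshold bases from each read's 3' end.

    The 3' end is in read orientation: the right end of the stored window
    for forward reads, the left end for reverse reads (coordinates stay
    reference-oriented). Reads trimmed to zero length are removed along
    with their mates.
    """
    if rs.n_reads == 0:
        return rs
    cols = np.arange(rs.qual.shape[1])
    ok = (rs.qual >= quality_threshold) & rs.valid_mask()
    rs = replace(
        rs,
        start=rs.start.copy(),
        length=rs.length.copy(),
        qoff=rs.qoff.copy(),
    )
    fwd = ~rs.is_reverse
    # forward: keep up to the last >=threshold base
    last_ok = np.max(np.where(ok, cols, -1), axis=1)
    new_len_f = np.where(last_ok >= 0, last_ok - rs.qoff + 1, 0).astype(np.int32)
    rs.length[fwd] = new_len_f[fwd]
    # reverse: trim the window head (reference-left = read 3')
    first_ok = np.min(np.where(ok, cols, np.iinfo(np.int64).max), axis=1)
    has = first_ok < np.iinfo(np.int64).max
    shift = np.where(has, first_ok - rs.qoff, rs.length).astype(np.int32)
    rev = rs.is_reverse
    rs.start[rev] += shift[rev]
    rs.qoff[rev] += shift[rev]
    rs.length[rev] -= shift[rev]
    return _drop_with_mates(rs, rs.length <= 0)


def mark_duplicates(rs: ReadSet) -> ReadSet:
    """Flag PCR/optical duplicates.

    Pairs sharing chromosome, fragment outer coordinates and strand
    configuration form one duplicate group; the pair with the highest
    summed base quality is kept (ties broken by lexicographically
    smallest pair name), the rest are flagged. Unpaired reads are grouped
    on their own (chrom, start, end, strand) key.
    """
    if rs.n_reads == 0:
        return rs
    out = replace(rs, is_dup=np.zeros(rs.n_reads, bool))
    sq = rs.summed_base_quality()
    names = np.array([rs.pair_name(i) for i in range(rs.n_reads)])

    def _flag(groups: dict, members_qual: dict) -> None:
        for key, rows in groups.items():
            if len(rows) < 2:
                continue
            best = min(rows, key=lambda r: (-members_qual[r], names[r[0] if isinstance(r, tuple) else r]))
            for r in rows:
                if r is best:
                    continue
                for idx in (r if isinstance(r, tuple) else (r,)):
                    out.is_dup[idx] = True

    pair_groups: dict[tuple, list] = {}
    qual_of: dict = {}
    seen_pair = np.zeros(rs.n_reads, bool)
    ends = rs.end
    for i in range(rs.n_reads):
        j = int(rs.mate[i])
        if j < 0 or seen_pair[i]:
            continue
        seen_pair[i] = seen_pair[j] = True
        lo, hi = (i, j) if rs.start[i] <= rs.start[j] else (j, i)
        key = (
            int(rs.chrom[i]),
            int(rs.start[lo]),
            int(max(ends[i], ends[j])),
            bool(rs.is_reverse[lo]),
            bool(rs.is_reverse[hi]),
        )
        member = (i, j)
        pair_groups.setdefault(key, []).append(member)
        qual_of[member] = int(sq[i] + sq[j])
    single_groups: dict[tuple, list] = {}
    for i in np.flatnonzero(rs.mate < 0):
        key = (int(rs.chrom[i]), int(rs.start[i]), int(ends[i]), bool(rs.is_reverse[i]))
        single_groups.setdefault(key, []).append(int(i))
        qual_of[int(i)] = int(sq[i])
    _flag(pair_groups, qual_of)
    _flag(single_groups, qual_of)
    return out


def downsample(rs: ReadSet, proportion: float, seed) -> DepthTier:
    """Thin read pairs by an independent Bernoulli(proportion) per pair.

    Both mates of a pair share one draw, so no orphan mates are produced.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must be in [0, 1]")
    if proportion == 1.0:
        return DepthTier(1.0, None, rs)
    rng = np.random.default_rng(seed)
    units = np.unique(rs.pair_id)
    kept_units = units[rng.random(units.size) < proportion]
    keep = np.isin(rs.pair_id, kept_units)
    return DepthTier(proportion, None, rs.take(np.flatnonzero(keep)))


def round_depth_label(depth: float) -> float:
    """2-dp half-up rounding used only for tier labels, not computation.

    The input is snapped to 10 decimals first so that binary-float dust
    (0.3 * 21.75 = 6.5249999...) does not flip the half-way rounding of
    what is exactly 6.525 in decimal.
    """
    return float(
        Decimal(repr(round(depth, 10))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def build_depth_ladder(
    rs: ReadSet, proportions, full_depth: float, seed
) -> list[DepthTier]:
    """Chained (nested) downsampling ladder.

    The tier at proportion p_i is thinned from the tier at p_{i+1} with
    ratio p_i / p_{i+1} (the largest from the full set), so tiers are
    nested subsets and curves computed along the ladder are monotone.
    The full read set is appended as the final tier (proportion 1).
    """
    props = [float(p) for p in proportions]
    if any(not (0.0 < p < 1.0) for p in props):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(props, props[1:])):
        raise ValueError("proportions must be strictly increasing")
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = base.spawn(len(props))
    tiers: list[DepthTier] = [DepthTier(1.0, float(full_depth), rs)]
    current, current_p = rs, 1.0
    for p, ss in zip(reversed(props), reversed(seeds)):
        tier = downsample(current, p / current_p, ss)
        tier = DepthTier(p, p * full_depth, tier.read_subset)
        tiers.append(tier)
        current, current_p = tier.read_subset, p
    tiers.reverse()
    return tiers


def compute_depth_and_coverage(
    tier: "DepthTier | ReadSet",
    genome: ReferenceGenome,
    exclude_duplicates: bool = True,
) -> tuple[float, float]:
    """(mean fold-depth, breadth) of a tier over the reference.

    mean depth = total aligned bases / genome length; breadth = fraction
    of reference positions overlapped by >=1 aligned base. Duplicate-
    flagged reads are excluded by default (Picard/GATK convention).
    """
    rs = tier.read_subset if isinstance(tier, DepthTier) else tier
    if genome.total_length == 0:
        raise ValueError("empty genome")
    use = rs.length > 0
    if exclude_duplicates:
        use &= ~rs.is_dup
    total_bases = int(rs.length[use].sum())
    covered = 0
    for ci, codes in enumerate(genome.codes):
        sel = use & (rs.chrom == ci)
        if not sel.any():
            continue
        diff = np.zeros(len(codes) + 1, dtype=np.int64)
        np.add.at(diff, rs.start[sel], 1)
        np.add.at(diff, rs.end[sel], -1)
        covered += int((np.cumsum(diff[:-1]) > 0).sum())
    return total_bases / genome.total_length, covered / genome.total_length
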