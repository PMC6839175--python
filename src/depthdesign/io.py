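"""Readers and writers for the standard interchange formats.

SAM (text, coordinate-sorted, with MC/MQ tags and pair/strand/duplicate
FLAG bits) carries reads; VCFv4.2 carries truth variants and calls;
plain TSV carries known sites, chip panels and metric tables. Real
SAM/VCF files can be supplied through the same readers; the SAM reader
reconstructs the sparse mismatch encoding against the given reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .genome import ReferenceGenome, decode_seq, encode_seq
from .readops import ReadSet
from .synthio import ChipPanel


# ---- FASTA ---------------------------------------------------------------


def write_fasta(genome: ReferenceGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(genome.chrom_names, genome.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> ReferenceGenome:
    names: list[str] = []
    chunks: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                names.append(line[1:].split()[0])
                chunks.append([])
            else:
                chunks[-1].append(line)
    return ReferenceGenome(names, [encode_seq("".join(c)) for c in chunks])


# ---- SAM -----------------------------------------------------------------


def write_sam(rs: ReadSet, genome: ReferenceGenome, path: str) -> None:
    """Coordinate-sorted SAM with full-match CIGARs and mate/duplicate flags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": n, "LN": len(c)}
            for n, c in zip(genome.chrom_names, genome.codes)
        ],
    }
    order = np.lexsort((rs.start, rs.chrom))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in order:
            i = int(i)
            a = pysam.AlignedSegment(out.header)
            a.query_name = rs.pair_name(i)
            a.reference_id = int(rs.chrom[i])
            a.reference_start = int(rs.start[i])
            a.mapping_quality = int(rs.mapq[i])
            a.cigarstring = f"{int(rs.length[i])}M"
            a.query_sequence = decode_seq(rs.bases(i, genome))
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rs.window_qual(i))
            )
            flag = 0
            j = int(rs.mate[i])
            if j >= 0:
                flag |= 0x1 | 0x2
                flag |= 0x40 if i < j else 0x80
                if rs.is_reverse[j]:
                    flag |= 0x20
                a.next_reference_id = int(rs.chrom[j])
                a.next_reference_start = int(rs.start[j])
                outer = int(max(rs.end[i], rs.end[j]) - min(rs.start[i], rs.start[j]))
                a.template_length = outer if rs.start[i] <= rs.start[j] else -outer
                a.set_tag("MC", f"{int(rs.length[j])}M")
                a.set_tag("MQ", int(rs.mapq[j]))
            if rs.is_reverse[i]:
                flag |= 0x10
            if rs.is_dup[i]:
                flag |= 0x400
            a.flag = flag
            out.write(a)


def read_sam(path: str, genome: ReferenceGenome) -> ReadSet:
    """Load a SAM/BAM file into a ReadSet, diffing bases vs the reference."""
    recs = []
    with pysam.AlignmentFile(path) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            recs.append(a)
    n = len(recs)
    row_len = max((a.query_length for a in recs), default=0)
    rs = ReadSet.empty(genome.chrom_names, row_len)
    if n == 0:
        return rs
    chrom = np.zeros(n, np.int16)
    start = np.zeros(n, np.int64)
    length = np.zeros(n, np.int32)
    is_rev = np.zeros(n, bool)
    mapq = np.zeros(n, np.uint8)
    is_dup = np.zeros(n, bool)
    qual = np.zeros((n, row_len), np.uint8)
    mm_read, mm_off, mm_base = [], [], []
    names: dict[str, list[int]] = {}
    for i, a in enumerate(recs):
        ci = genome.chrom_index(a.reference_name)
        chrom[i] = ci
        start[i] = a.reference_start
        length[i] = a.query_length
        is_rev[i] = a.is_reverse
        mapq[i] = a.mapping_quality
        is_dup[i] = a.is_duplicate
        qual[i, : a.query_length] = np.asarray(a.query_qualities, np.uint8)
        seq = encode_seq(a.query_sequence)
        ref = genome.codes[ci][a.reference_start : a.reference_start + a.query_length]
        diff = np.flatnonzero(seq != ref)
        mm_read += [i] * diff.size
        mm_off += diff.tolist()
        mm_base += seq[diff].tolist()
        names.setdefault(a.query_name, []).append(i)
    pair_id = np.zeros(n, np.int64)
    mate = np.full(n, -1, np.int64)
    for k, (_, rows) in enumerate(sorted(names.items())):
        for r in rows:
            pair_id[r] = k
        if len(rows) == 2:
            mate[rows[0]], mate[rows[1]] = rows[1], rows[0]
    order = np.lexsort((mm_off, mm_read)) if mm_read else np.empty(0, np.int64)
    return ReadSet(
        chrom_names=genome.chrom_names,
        chrom=chrom,
        start=start,
        length=length,
        qoff=np.zeros(n, np.int32),
        is_reverse=is_rev,
        mapq=mapq,
        is_dup=is_dup,
        pair_id=pair_id,
        mate=mate,
        qual=qual,
        mm_read=np.asarray(mm_read, np.int64)[order],
        mm_off=np.asarray(mm_off, np.int32)[order],
        mm_base=np.asarray(mm_base, np.uint8)[order],
    )


# ---- VCF -----------------------------------------------------------------

_INFO_FIELDS = [
    ("QD", "1", "Float", "Variant quality over depth of alt-carrying samples"),
    ("FS", "1", "Float", "Phred-scaled two-sided Fisher strand p-value"),
    ("MQ", "1", "Float", "RMS mapping quality"),
    ("MQRankSum", "1", "Float", "Mann-Whitney z of alt vs ref mapping quality"),
    ("ReadPosRankSum", "1", "Float", "Mann-Whitney z of alt vs ref read position"),
    ("AC", "A", "Integer", "Alternate allele count in called genotypes"),
    ("AN", "1", "Integer", "Number of called alleles"),
    ("DP", "1", "Integer", "Combined read depth"),
]


def write_vcf(calls: pd.DataFrame, genome: ReferenceGenome, path: str) -> None:
    """Write a calls frame as VCFv4.2 with GT:PL:DP per-sample fields."""
    samples = calls.attrs.get("samples") or [
        c[3:] for c in calls.columns if c.startswith("GT_")
    ]
    header = pysam.VariantHeader()
    for name, codes in zip(genome.chrom_names, genome.codes):
        header.contigs.add(name, length=len(codes))
    for key, num, typ, desc in _INFO_FIELDS:
        header.info.add(key, num, typ, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.formats.add("DP", "1", "Integer", "Read depth")
    filters = set()
    for f in calls.get("filter", pd.Series(dtype=str)).dropna():
        for name in str(f).split(";"):
            if name not in (".", "PASS", ""):
                filters.add(name)
    for name in sorted(filters):
        header.filters.add(name, None, None, "Hard-filter clause failed")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for _, row in calls.iterrows():
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(row["ref"]),
                alleles=(row["ref"], row["alt"]),
                qual=float(row["qual"]) if "qual" in row else None,
            )
            for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
                v = row.get(key)
                if v is not None and pd.notna(v):
                    rec.info[key] = float(v)
            for key in ("AC", "AN", "DP"):
                v = row.get(key)
                if v is not None and pd.notna(v):
                    rec.info[key] = int(v) if key != "AC" else (int(v),)
            f = str(row.get("filter", "."))
            if f == "PASS":
                rec.filter.add("PASS")
            elif f not in (".", "nan", ""):
                for name in f.split(";"):
                    rec.filter.add(name)
            for s in samples:
                g = int(row.get(f"GT_{s}", -1))
                rec.samples[s]["GT"] = (
                    (None, None) if g < 0 else ((0, 0), (0, 1), (1, 1))[g]
                )
                pl = row.get(f"PL_{s}")
                if isinstance(pl, str) and pl:
                    rec.samples[s]["PL"] = tuple(int(x) for x in pl.split(","))
                dp = row.get(f"DP_{s}")
                if dp is not None and pd.notna(dp):
                    rec.samples[s]["DP"] = int(dp)
            out.write(rec)


def read_vcf(path: str) -> pd.DataFrame:
    """Load a VCF into the calls-frame layout used across the package."""
    rows = []
    with pysam.VariantFile(path) as fh:
        samples = list(fh.header.samples)
        for rec in fh:
            alt = rec.alts[0] if rec.alts else "."
            vclass = "SNP"
            if len(rec.ref) > len(alt):
                vclass = "DEL"
            elif len(alt) > len(rec.ref):
                vclass = "INS"
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt,
                "vclass": vclass,
                "qual": rec.qual,
                "filter": ";".join(rec.filter.keys()) or ".",
            }
            for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "AN", "DP"):
                if key in rec.info:
                    row[key] = rec.info[key]
            if "AC" in rec.info:
                ac = rec.info["AC"]
                row["AC"] = int(ac[0] if isinstance(ac, tuple) else ac)
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or gt[0] is None:
                    row[f"GT_{s}"] = -1
                else:
                    row[f"GT_{s}"] = int(sum(gt))
                if rec.samples[s].get("DP") is not None:
                    row[f"DP_{s}"] = int(rec.samples[s]["DP"])
                pl = rec.samples[s].get("PL")
                if pl is not None:
                    row[f"PL_{s}"] = ",".join(str(int(x)) for x in pl)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["samples"] = samples
    return df


# ---- TSV sidecars --------------------------------------------------------


def write_known_sites_tsv(known: pd.DataFrame, path: str) -> None:
    known[["chrom", "pos", "ref", "alt"]].to_csv(path, sep="\t", index=False)


def read_known_sites_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chip_tsv(panel: ChipPanel, sample_names, site_path: str, geno_path: str) -> None:
    panel.sites.to_csv(site_path, sep="\t", index=False)
    pd.DataFrame(
        panel.genotypes.T, columns=list(sample_names)
    ).to_csv(geno_path, sep="\t", index=False)


def read_chip_tsv(site_path: str, geno_path: str) -> tuple[ChipPanel, list[str]]:
    sites = pd.read_csv(site_path, sep="\t")
    geno = pd.read_csv(geno_path, sep="\t")
    return ChipPanel(sites, geno.to_numpy(np.int8).T), list(geno.columns)
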