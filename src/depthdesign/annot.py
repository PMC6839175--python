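"""Gene-model annotation: exon membership and loss-of-function classes.

A variant is classified against each overlapping gene model as one of
three LoF categories (or none): frameshift (an indel in coding sequence
whose length change is not a multiple of 3), splice_site (a variant in
the first or second intronic base flanking an exon boundary — the
canonical donor/acceptor dinucleotides), or stopgain/stoploss (an SNV
whose strand-aware codon change creates or destroys a stop codon under
the standard genetic code). Start-loss is deliberately not classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import ReferenceGenome


@dataclass
class GeneModel:
    """A single-transcript gene: sorted, non-overlapping 1-based intervals."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 1-based inclusive
    cds: list[tuple[int, int]]  # subset of the exon footprint

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for ivs in (self.exons, self.cds):
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c <= b:
                    raise ValueError(f"{self.gene_id}: intervals overlap or unsorted")
        exon_pos = set()
        for a, b in self.exons:
            exon_pos.update(range(a, b + 1))
        for a, b in self.cds:
            if not set(range(a, b + 1)) <= exon_pos:
                raise ValueError(f"{self.gene_id}: CDS outside exons")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def contains_exonic(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.exons)

    def cds_coordinate(self, pos: int) -> int | None:
        """0-based position within the spliced CDS in translation order."""
        offset = 0
        if self.strand == "+":
            for a, b in self.cds:
                if a <= pos <= b:
                    return offset + (pos - a)
                offset += b - a + 1
        else:
            for a, b in reversed(self.cds):
                if a <= pos <= b:
                    return offset + (b - pos)
                offset += b - a + 1
        return None

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        parts = [genome.slice(self.chrom, a, b) for a, b in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def splice_positions(self) -> set[int]:
        """Intronic positions 1-2 bases from each internal exon boundary."""
        out: set[int] = set()
        for i, (a, b) in enumerate(self.exons):
            if i > 0:  # acceptor side
                out.update((a - 2, a - 1))
            if i < len(self.exons) - 1:  # donor side
                out.update((b + 1, b + 2))
        return out


@dataclass
class VariantAnnotation:
    exonic: bool
    lof_class: str  # frameshift | splice_site | stopgain | stoploss | none
    gene_id: str | None = None


def _in_cds(model: GeneModel, pos: int) -> bool:
    return any(a <= pos <= b for a, b in model.cds)


def classify_variant(variant, model: GeneModel, genome: ReferenceGenome) -> VariantAnnotation:
    """Classify one variant (mapping or row with chrom/pos/ref/alt) vs a gene.

    Precedence when several categories could apply: frameshift for
    out-of-frame coding indels, then splice_site, then stopgain/stoploss
    for coding SNVs.
    """
    chrom = variant["chrom"]
    pos = int(variant["pos"])
    ref, alt = variant["ref"], variant["alt"]
    if chrom != model.chrom:
        raise ValueError("variant is not on the gene model's chromosome")
    exonic = model.contains_exonic(pos)
    is_indel = len(ref) != len(alt)
    none = VariantAnnotation(exonic, "none", model.gene_id)

    if is_indel:
        # anchored representation: the changed bases start after the anchor
        affected = range(pos + 1, pos + max(len(ref), len(alt)))
        if any(_in_cds(model, p) for p in affected) and (len(ref) - len(alt)) % 3 != 0:
            return VariantAnnotation(exonic, "frameshift", model.gene_id)
        if any(p in model.splice_positions() for p in affected):
            return VariantAnnotation(exonic, "splice_site", model.gene_id)
        return none

    if pos in model.splice_positions():
        return VariantAnnotation(exonic, "splice_site", model.gene_id)
    if not _in_cds(model, pos):
        return none
    cpos = model.cds_coordinate(pos)
    cds = model.cds_sequence(genome)
    codon_i = cpos // 3
    codon = list(cds[codon_i * 3 : codon_i * 3 + 3])
    within = cpos % 3
    new_base = alt if model.strand == "+" else str(Seq(alt).complement())
    old = str(Seq("".join(codon)).translate())
    codon[within] = new_base
    new = str(Seq("".join(codon)).translate())
    if old != "*" and new == "*":
        return VariantAnnotation(True, "stopgain", model.gene_id)
    if old == "*" and new != "*":
        return VariantAnnotation(True, "stoploss", model.gene_id)
    return none


def count_annotations(
    calls: pd.DataFrame, models: list[GeneModel], genome: ReferenceGenome
) -> tuple[int, int]:
    """(n_exonic, n_lof) over all calls; a variant counts once even when
    several models flag it."""
    n_exonic = 0
    n_lof = 0
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for _, v in calls.iterrows():
        exonic = False
        lof = False
        for m in by_chrom.get(v["chrom"], []):
            ann = classify_variant(v, m, genome)
            exonic |= ann.exonic
            lof |= ann.lof_class != "none"
        n_exonic += int(exonic)
        n_lof += int(lof)
    return n_exonic, n_lof


# --------------------------------------------------------------------------
# toy gene-model generation and GFF3 round-trip


def simulate_gene_models(
    genome: ReferenceGenome, n_genes: int = 20, seed=0, exon_len: int = 120,
    intron_len: int = 300, n_exons: int = 3,
) -> list[GeneModel]:
    """Evenly spaced toy genes with fixed exon/intron geometry.

    Exon length is a multiple of 3 so each whole exon stack is a valid
    CDS; strands alternate so both orientations get exercised.
    """
    if exon_len % 3 != 0:
        raise ValueError("exon_len must be a multiple of 3")
    rng = np.random.default_rng(seed)
    models = []
    span = n_exons * exon_len + (n_exons - 1) * intron_len
    for ci, name in enumerate(genome.chrom_names):
        L = len(genome.codes[ci])
        slots = max((L - 1000) // (span + 2000), 0)
        take = min(n_genes - len(models), slots)
        for g in range(take):
            start = 500 + g * (span + 2000) + int(rng.integers(0, 500))
            exons = [
                (start + k * (exon_len + intron_len),
                 start + k * (exon_len + intron_len) + exon_len - 1)
                for k in range(n_exons)
            ]
            strand = "+" if (len(models) % 2 == 0) else "-"
            models.append(
                GeneModel(f"gene{len(models) + 1}", name, strand, exons, list(exons))
            )
        if len(models) >= n_genes:
            break
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(a for a, _ in m.exons)
            hi = max(b for _, b in m.exons)
            fh.write(
                f"{m.chrom}\tdepthdesign\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\tdepthdesign\texon\t{a}\t{b}\t.\t{m.strand}\t.\tParent={m.gene_id}\n"
                )
            frame = 0
            for a, b in (m.cds if m.strand == "+" else list(reversed(m.cds))):
                fh.write(
                    f"{m.chrom}\tdepthdesign\tCDS\t{a}\t{b}\t.\t{m.strand}\t{frame}\tParent={m.gene_id}\n"
                )
                frame = (3 - ((b - a + 1 - frame) % 3)) % 3


def read_gff3(path: str) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[info["ID"]] = {
                    "chrom": chrom, "strand": strand, "exons": [], "cds": []
                }
            elif ftype in ("exon", "CDS"):
                g = genes[info["Parent"]]
                g["exons" if ftype == "exon" else "cds"].append((int(start), int(end)))
    return [
        GeneModel(gid, g["chrom"], g["strand"], sorted(g["exons"]), sorted(g["cds"]))
        for gid, g in genes.items()
    ]
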