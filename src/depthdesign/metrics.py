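"""Depth-response and validation metrics.

Variant identity throughout is the exact (chrom, pos, ref, alt) tuple.
Definitions:

* discovery power — fraction of the deepest-tier call set recovered at a
  shallower tier, |tier ∩ full| / |full| (intersection form, so the
  value is a true fraction and equals 1 at the full tier).
* novel rate — fraction of calls absent from the known-sites list.
* Ti/Tv — transitions (A<->G, C<->T) over transversions, SNPs only.
* chip QC — drop array sites with call rate below a threshold (>= keeps).
* common sites — call positions intersected with array positions;
  ``alt_only`` further requires the sample's called genotype to carry at
  least one non-reference allele (the "m-calling-Alt" convention).
* discordance rate — genotype mismatches / common sites, comparing
  unphased allele sets; chip-missing genotypes are excluded from both
  numerator and denominator. Single-sample mode uses all common sites,
  multisample mode the alt-only set.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .synthio import ChipPanel

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

VariantKey = tuple[str, int, str, str]


def variant_keys(calls: "pd.DataFrame | Iterable[VariantKey]") -> set[VariantKey]:
    """Normalize a calls frame (or iterable of tuples) to a key set."""
    if isinstance(calls, pd.DataFrame):
        if len(calls) == 0:
            return set()
        return set(
            zip(calls["chrom"], calls["pos"].astype(int), calls["ref"], calls["alt"])
        )
    return set(calls)


def discovery_power(tier_calls, full_depth_calls) -> Optional[float]:
    full = variant_keys(full_depth_calls)
    if not full:
        return None
    return len(variant_keys(tier_calls) & full) / len(full)


def novel_rate(calls, known_sites) -> Optional[float]:
    """Fraction of calls whose (chrom, pos) is absent from the known list.

    Membership is positional (a dbSNP-style lookup), so a call at a known
    site with a different alternate still counts as known.
    """
    keys = variant_keys(calls)
    if not keys:
        return None
    known = known_positions(known_sites)
    missing = sum(1 for k in keys if (k[0], k[1]) not in known)
    return missing / len(keys)


def known_positions(known_sites) -> set[tuple[str, int]]:
    if isinstance(known_sites, pd.DataFrame):
        return set(zip(known_sites["chrom"], known_sites["pos"].astype(int)))
    return {(k[0], k[1]) for k in known_sites}


def titv_ratio(calls) -> Optional[float]:
    """Transitions / transversions over SNP records; absent when no Tv."""
    if isinstance(calls, pd.DataFrame):
        snps = calls[calls["vclass"] == "SNP"] if "vclass" in calls else calls
        pairs = list(zip(snps["ref"], snps["alt"]))
    else:
        pairs = [(k[2], k[3]) for k in variant_keys(calls)]
    pairs = [p for p in pairs if len(p[0]) == 1 and len(p[1]) == 1]
    ti = sum(1 for p in pairs if p in TRANSITIONS)
    tv = len(pairs) - ti
    if tv == 0:
        return None
    return ti / tv


def chip_qc(panel: ChipPanel, min_call_rate: float = 0.95, chrom_names=None) -> ChipPanel:
    """Retain sites with call_rate >= min_call_rate on declared chromosomes."""
    ok = panel.sites["call_rate"].to_numpy() >= min_call_rate
    if chrom_names is not None:
        ok &= panel.sites["chrom"].isin(list(chrom_names)).to_numpy()
    idx = np.flatnonzero(ok)
    return ChipPanel(
        panel.sites.iloc[idx].reset_index(drop=True),
        panel.genotypes[:, idx] if panel.genotypes.size else panel.genotypes,
    )


def common_sites(
    calls: pd.DataFrame, panel: ChipPanel, mode: str = "all", sample: Optional[str] = None
) -> set[tuple[str, int]]:
    """Call positions shared with the (QC'd) panel.

    mode='alt_only' keeps only sites where ``sample``'s called genotype
    carries at least one non-reference allele.
    """
    if mode not in ("all", "alt_only"):
        raise ValueError("mode must be 'all' or 'alt_only'")
    if len(calls) == 0:
        return set()
    df = calls
    if mode == "alt_only":
        if sample is None:
            raise ValueError("alt_only mode needs a sample")
        df = calls[calls[f"GT_{sample}"] > 0]
    pos = set(zip(df["chrom"], df["pos"].astype(int)))
    return pos & panel.positions()


def discordance_rate(
    calls: pd.DataFrame,
    panel: ChipPanel,
    sample: str,
    mode: str = "single",
    sample_idx: Optional[int] = None,
) -> Optional[float]:
    """Genotype discordance against the array at shared sites.

    single mode divides mismatches by all common sites; multi mode by the
    common sites where the sample's call carries a non-reference allele.
    A mismatch is any unphased allele-set difference (het vs hom-alt
    counts); sites with a missing chip genotype are dropped entirely.
    ``sample_idx`` maps the sample onto a panel genotype row; by default
    it is looked up in calls.attrs['panel_samples'] (or 'samples').
    """
    site_mode = "all" if mode == "single" else "alt_only"
    shared = common_sites(calls, panel, mode=site_mode, sample=sample)
    if not shared:
        return None
    if sample_idx is None:
        sample_idx = _panel_sample_index(panel, calls, sample)
    chip_pos = {
        (c, int(p)): k
        for k, (c, p) in enumerate(zip(panel.sites["chrom"], panel.sites["pos"]))
    }
    call_gt = {
        (c, int(p)): (int(g), a)
        for c, p, g, a in zip(
            calls["chrom"], calls["pos"], calls[f"GT_{sample}"], calls["alt"]
        )
    }
    allele_b = panel.sites["allele_b"].to_numpy()
    n_used = 0
    mismatches = 0
    for site in shared:
        k = chip_pos[site]
        chip_g = int(panel.genotypes[sample_idx, k])
        if chip_g < 0:
            continue
        n_used += 1
        g, alt = call_gt[site]
        if g > 0 and alt != allele_b[k]:
            mismatches += 1
        elif g != chip_g:
            mismatches += 1
    if n_used == 0:
        return None
    return mismatches / n_used


def _panel_sample_index(panel: ChipPanel, calls: pd.DataFrame, sample: str) -> int:
    samples = calls.attrs.get("samples")
    names = calls.attrs.get("panel_samples") or samples
    if names and sample in names:
        return list(names).index(sample)
    raise KeyError(f"sample {sample!r} not mapped to a panel row")


def genotype_concordance(
    calls: pd.DataFrame, truth, genotypes: np.ndarray, sample: str, sample_idx: int
) -> Optional[float]:
    """Fraction of called sites that are truth sites with matching dosage."""
    if len(calls) == 0:
        return None
    truth_gt = {
        (c, int(p), r, a): int(genotypes[i, sample_idx])
        for i, (c, p, r, a) in enumerate(
            zip(truth["chrom"], truth["pos"], truth["ref"], truth["alt"])
        )
    }
    hits = 0
    total = 0
    for c, p, r, a, g in zip(
        calls["chrom"], calls["pos"], calls["ref"], calls["alt"], calls[f"GT_{sample}"]
    ):
        key = (c, int(p), r, a)
        if key not in truth_gt:
            continue
        total += 1
        hits += int(int(g) == truth_gt[key])
    if total == 0:
        return None
    return hits / total


def fold_change_multi_vs_single(multi_common: int, single_common: int) -> Optional[float]:
    if single_common == 0:
        return None
    return multi_common / single_common


def intersect_populations(call_sets: dict[str, "pd.DataFrame | set"]) -> dict[str, int]:
    """Pairwise and full overlap counts across population call sets."""
    if len(call_sets) < 2:
        raise ValueError("need at least two populations")
    keys = {name: variant_keys(cs) for name, cs in call_sets.items()}
    names = list(keys)
    out: dict[str, int] = {name: len(keys[name]) for name in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}&{b}"] = len(keys[a] & keys[b])
    full = set.intersection(*keys.values())
    out["&".join(names)] = len(full)
    return out
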