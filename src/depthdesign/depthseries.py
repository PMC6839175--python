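"""Orchestration of the depth-titration experiment and curve analysis.

For every individual the pipeline runs: read QC -> 3' trim -> duplicate
marking -> chained (nested) downsampling to the configured proportions
-> single-sample calling per tier, plus joint multisample calling per
tier across the cohort -> hard filtering -> metrics (realized depth,
breadth, variant counts, discovery power vs the full tier, novel rate,
Ti/Tv, chip common sites and discordance). Curves along the nested
ladder are then summarized with a plateau rule (first depth within
epsilon of the terminal value) and a discrete inflection rule (most
negative second difference of the curve on the observed grid), and
compared against the analytic Lander-Waterman breadth 1 - exp(-depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from .caller import call_variants
from .readops import (
    DepthTier,
    build_depth_ladder,
    compute_depth_and_coverage,
    mark_duplicates,
    qc_filter_reads,
    round_depth_label,
    trim_3prime,
)
from .synthio import PAPER_PROPORTIONS, SyntheticCohort, simulate_reads
from .vfilter import INDEL_HARD_FILTER, SNP_HARD_FILTER, apply_hard_filter, pass_only


def lander_waterman_breadth(depth) -> "float | np.ndarray":
    """Expected covered fraction under uniform sequencing: 1 - e^(-depth)."""
    d = np.asarray(depth, dtype=float)
    if (d < 0).any():
        raise ValueError("depth must be non-negative")
    out = 1.0 - np.exp(-d)
    return float(out) if out.ndim == 0 else out


def find_plateau(depths, values, epsilon: float = 0.005) -> Optional[float]:
    """Smallest depth whose value reaches (1-epsilon) x the terminal value."""
    d = np.asarray(depths, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size < 3 or (np.diff(d) <= 0).any():
        raise ValueError("need >=3 points with increasing depths")
    target = (1.0 - epsilon) * v[-1]
    qual = np.flatnonzero(v >= target)
    if qual.size == 0:
        return None
    return float(d[qual[0]])


def find_inflection(depths, values, tol: float = 1e-9) -> Optional[float]:
    """Depth with the sharpest drop in forward slope (discrete curvature).

    Slopes are taken between consecutive observed points; the returned
    depth is the interior point whose incoming-vs-outgoing slope change
    is most negative. Absent when no change is below -tol (e.g. a linear
    curve). Ties resolve to the earliest depth.
    """
    d = np.asarray(depths, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size < 4 or (np.diff(d) <= 0).any():
        raise ValueError("need >=4 points with increasing depths")
    slopes = np.diff(v) / np.diff(d)
    d2 = np.diff(slopes)  # assigned to interior depths d[1:-1]
    m = d2.min()
    if m >= -tol:
        return None
    idx = int(np.flatnonzero(d2 <= m + abs(m) * 1e-9)[0])
    return float(d[idx + 1])


@dataclass
class DepthSeriesReport:
    """Per-tier metric rows plus curve summaries."""

    rows: pd.DataFrame
    plateau_depth: dict[str, Optional[float]] = field(default_factory=dict)
    inflection_depth: dict[str, Optional[float]] = field(default_factory=dict)
    lw_expected_breadth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path: str) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def curve(self, metric: str, mode: str = "single") -> pd.DataFrame:
        """Mean of a metric across samples per tier, sorted by depth."""
        sub = self.rows[self.rows["mode"] == mode]
        g = sub.groupby("nominal_depth", as_index=False)[metric].mean()
        return g.sort_values("nominal_depth", ignore_index=True)


def run_depth_series(
    cohort: SyntheticCohort,
    proportions: Sequence[float] = PAPER_PROPORTIONS,
    modes: Sequence[str] = ("single", "multi"),
    *,
    theta: float = 1e-3,
    emit_conf: float = 30.0,
    seed: int = 0,
    snp_filter: str = SNP_HARD_FILTER,
    indel_filter: str = INDEL_HARD_FILTER,
    chip_min_call_rate: float = 0.95,
    apply_read_qc: bool = True,
    pass_only_metrics: bool = True,
) -> DepthSeriesReport:
    """Run the full titration and return the metric table.

    Deterministic in (cohort.config.seed, seed): reads are a function of
    the cohort seed, ladder thinning of ``seed``.
    """
    cfg = cohort.config
    genome = cohort.genome
    names = cohort.sample_names
    indels = cohort.truth_indels()[["chrom", "pos", "ref", "alt", "vclass"]]
    panel = M.chip_qc(cohort.chip, chip_min_call_rate, genome.chrom_names)
    known = cohort.known_sites

    ladders: dict[str, list[DepthTier]] = {}
    for i, s in enumerate(names):
        rs = simulate_reads(cohort, i)
        if apply_read_qc:
            rs = qc_filter_reads(rs)
            rs = trim_3prime(rs)
        rs = mark_duplicates(rs)
        ladder_seed = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        ladders[s] = build_depth_ladder(rs, proportions, cfg.mean_depth, ladder_seed)

    n_tiers = len(ladders[names[0]])
    rows: list[dict] = []
    full_sets: dict[tuple[str, str], set] = {}  # (mode, sample) -> PASS SNP keys

    def _select(calls: pd.DataFrame) -> pd.DataFrame:
        return pass_only(calls) if pass_only_metrics else calls

    for ti in reversed(range(n_tiers)):  # full tier first (discovery power)
        tier0 = ladders[names[0]][ti]
        depth_cov = {
            s: compute_depth_and_coverage(ladders[s][ti], genome) for s in names
        }
        units: list[tuple[str, dict]] = []
        if "multi" in modes and len(names) > 1:
            units.append(("multi", {s: ladders[s][ti].read_subset for s in names}))
        if "single" in modes:
            units += [("single", {s: ladders[s][ti].read_subset}) for s in names]
        for mode, readsets in units:
            calls = call_variants(
                readsets, genome, theta=theta, emit_conf=emit_conf, indel_sites=indels
            )
            calls = apply_hard_filter(calls, snp_filter, indel_filter)
            calls.attrs["panel_samples"] = names
            used = _select(calls)
            snps = used[used["vclass"] == "SNP"]
            keys = M.variant_keys(snps)
            for s in readsets:
                unit_key = (mode, s if mode == "single" else "cohort")
                if ti == n_tiers - 1:
                    full_sets[unit_key] = keys
                row = {
                    "sample": s,
                    "mode": mode,
                    "proportion": tier0.proportion,
                    "nominal_depth": round_depth_label(
                        tier0.proportion * cfg.mean_depth
                    ),
                    "realized_depth": depth_cov[s][0],
                    "breadth": depth_cov[s][1],
                    "n_variants": len(snps),
                    "n_variants_all": int((calls["vclass"] == "SNP").sum()),
                    "discovery_power": M.discovery_power(keys, full_sets[unit_key]),
                    "novel_rate": M.novel_rate(snps, known),
                    "titv": M.titv_ratio(snps),
                    "chip_common_all": len(
                        M.common_sites(used, panel, "all", s)
                    ),
                    "chip_common_alt": len(
                        M.common_sites(used, panel, "alt_only", s)
                    ),
                    "discordance": M.discordance_rate(
                        used, panel, s, mode=mode, sample_idx=names.index(s)
                    ),
                }
                rows.append(row)

    df = pd.DataFrame(rows).sort_values(
        ["mode", "sample", "nominal_depth"], ignore_index=True
    )
    report = DepthSeriesReport(rows=df)
    for metric in ("breadth", "discovery_power", "n_variants"):
        for mode in dict.fromkeys(df["mode"]):
            curve = report.curve(metric, mode)
            d, v = curve["nominal_depth"].to_numpy(), curve[metric].to_numpy()
            key = f"{metric}/{mode}"
            if d.size >= 3 and np.isfinite(v).all():
                report.plateau_depth[key] = find_plateau(d, v)
            if d.size >= 4 and np.isfinite(v).all():
                report.inflection_depth[key] = find_inflection(d, v)
    depth_curve = report.curve("realized_depth", df["mode"].iloc[0])
    report.lw_expected_breadth = pd.DataFrame(
        {
            "nominal_depth": depth_curve["nominal_depth"],
            "expected_breadth": lander_waterman_breadth(
                depth_curve["realized_depth"].to_numpy()
            ),
        }
    )
    return report
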