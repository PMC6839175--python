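#!/usr/bin/env python
"""Multisample vs single-sample calling against the chip panel.

Post-processes the depth-series table (run 03_depth_series.py first):
per tier, the mean chip common-site count for single-sample calling and
for multisample calling (all sites, and sites with at least one
non-reference allele), the multi/single fold change, and the mean
discordance of each calling strategy.
"""

from pathlib import Path

import pandas as pd

from depthdesign.metrics import fold_change_multi_vs_single

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    src = RESULTS / "depth_series.tsv"
    if not src.exists():
        raise SystemExit("run analysis/03_depth_series.py first")
    rows = pd.read_csv(src, sep="\t")
    out_rows = []
    for depth, grp in rows.groupby("nominal_depth"):
        single = grp[grp["mode"] == "single"]
        multi = grp[grp["mode"] == "multi"]
        s_common = single["chip_common_all"].mean()
        m_all = multi["chip_common_all"].mean()
        m_alt = multi["chip_common_alt"].mean()
        out_rows.append({
            "nominal_depth": depth,
            "s_calling_common": round(s_common, 1),
            "m_calling_all_common": round(m_all, 1),
            "m_calling_alt_common": round(m_alt, 1),
            "fold_change_all": round(
                fold_change_multi_vs_single(m_all, s_common) or float("nan"), 3),
            "fold_change_alt": round(
                fold_change_multi_vs_single(m_alt, s_common) or float("nan"), 3),
            "s_calling_discordance": round(single["discordance"].mean(), 5),
            "m_calling_discordance": round(multi["discordance"].mean(), 5),
        })
    df = pd.DataFrame(out_rows).sort_values("nominal_depth")
    out = RESULTS / "chip_comparison.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
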