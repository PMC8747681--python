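#!/usr/bin/env python
"""Storage-trend statistics: per-trait ANOVA on genotype and year, and
genotype-centered Pearson correlations with the three year encodings,
with the 2000-replicate permutation + bootstrap envelope rule on the
YearRank encoding (results/study/trend.csv, anova.csv)."""

import argparse
from pathlib import Path

import pandas as pd

from grainaging.config import StudyConfig
from grainaging.pipeline import stage_analyze


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    ap.add_argument("--n-rep", type=int, default=2000)
    args = ap.parse_args()

    cfg = StudyConfig.from_json(args.outdir / "config.json")
    stage_analyze(cfg, args.outdir, n_rep=args.n_rep)

    trend = pd.read_csv(args.outdir / "trend.csv")
    yr = trend[trend.scheme == "YearRank"].set_index("trait")
    sig = yr[yr.significant.eq(True)]
    print(f"significant YearRank trends: {len(sig)} of {len(yr)} traits")
    print("\nstrongest negative trends (storage-associated redness):")
    print(sig.nsmallest(5, "r")[["r", "perm_min", "perm_max",
                                 "boot_min", "boot_max"]].round(3))
    print("\nstrongest positive trends:")
    print(sig.nlargest(3, "r")[["r", "perm_min", "perm_max"]].round(3))

    anova = pd.read_csv(args.outdir / "anova.csv")
    by_factor = anova.assign(sig=anova.p < 0.05).groupby("factor")["sig"].sum()
    print("\ntraits with significant ANOVA (p < 0.05):",
          by_factor.to_dict(), f"of {yr.shape[0]}")


if __name__ == "__main__":
    main()
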